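"""Event-driven simulation of canonical non-homologous end joining (c-NHEJ).

Each DSB contributes two mobile broken ends.  Ends move by a sub-diffusive
continuous-time random walk: a waiting time is drawn from an exponential
distribution, after which the end jumps by a Gaussian-length step in a
uniformly random direction (steps leaving the nuclear envelope are rejected
and resampled).  Successive waiting-time means grow with the number of
completed steps (``wait_mean · (k+1)^((1-α)/α)``), an aging scheme that keeps
every individual draw exponential while making the ensemble mean squared
displacement scale as ``t^α`` with ``α < 1``.

Concurrently every end walks a protein-recruitment state machine::

    NAKED ⇄ INHIBITED          (competing-pathway occupation, reversible)
    NAKED → KU → DNAPK         (Ku70/80 then DNA-PKcs; irreversible)
    DNAPK + DNAPK → LONG_SYNAPSE   (pairwise, ends within 25 nm)
    LONG_SYNAPSE → NAKED + NAKED   (dissociation, τ = 95 s)
    LONG_SYNAPSE → SHORT_SYNAPSE → CLEANING → LIGATED

All holding times are exponential with configurable means.  A ligated pair
whose two ends originate from the same DSB is a correct repair; otherwise it
is a misrepair (the proxy for chromosome aberration).  A DSB with an
unligated end at the end of the run (default 24 h) is residual.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .damage_generation import DamagePattern, Nucleus

__all__ = [
    "StateEnum",
    "MotionParams",
    "KineticConfig",
    "DsbEnd",
    "RepairOutcome",
    "RepairSimulation",
    "run_repair",
    "free_motion_msd",
]

DAY_S = 86400.0


class StateEnum(Enum):
    NAKED = "naked"
    INHIBITED = "inhibited"
    KU = "ku"
    DNAPK = "dnapk"
    LONG_SYNAPSE = "long_synapse"
    SHORT_SYNAPSE = "short_synapse"
    CLEANING = "cleaning"
    LIGATED = "ligated"


#: states in which an end moves freely
_MOBILE = frozenset(
    {StateEnum.NAKED, StateEnum.INHIBITED, StateEnum.KU, StateEnum.DNAPK}
)


@dataclass(frozen=True)
class MotionParams:
    """Sub-diffusive CTRW motion parameters.

    ``wait_mean``: mean (s) of the first exponential waiting time; the mean
    of the k-th wait is ``wait_mean·(k+1)^((1-alpha)/alpha)`` so the ensemble
    MSD grows as t^alpha.  ``step_sigma``: Gaussian step-length scale (nm);
    a value of 0 disables motion entirely.  ``duration_cap_s`` optionally
    freezes ends after that much simulated time.

    Defaults are calibrated jointly with :class:`KineticConfig` so that 95 %
    of break ends move less than ~168 nm in 24 h and ~7.3 % of breaks remain
    unrepaired.
    """

    wait_mean: float = 2.0
    step_sigma: float = 9.5
    alpha: float = 0.61
    duration_cap_s: float | None = None

    def __post_init__(self) -> None:
        if self.wait_mean <= 0:
            raise ValueError("wait_mean must be positive")
        if self.step_sigma < 0:
            raise ValueError("step_sigma must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1) for sub-diffusion")

    @property
    def aging_exponent(self) -> float:
        return (1.0 - self.alpha) / self.alpha

    def wait_scale(self, k_steps: int) -> float:
        return self.wait_mean * (k_steps + 1) ** self.aging_exponent


@dataclass(frozen=True)
class KineticConfig:
    """Exponential time constants (s) of the c-NHEJ state machine.

    ``tau_phosphorylation`` (95 s) is the DNA-PK auto-phosphorylation clock
    that dissolves a long-range synaptic complex; it *is* the dissociation
    constant ``tau_long_dissociate`` unless the latter is set explicitly.
    Use ``math.inf`` to disable a channel (e.g. ``tau_inhibit_on=inf``
    switches competing-pathway inhibition off).
    """

    tau_inhibit_on: float = 1000.0
    tau_inhibit_off: float = 60.0
    tau_ku: float = 0.5
    tau_dnapk: float = 2.0
    tau_phosphorylation: float = 95.0
    tau_long_dissociate: float | None = None
    tau_long_advance: float = 200.0
    tau_clean_per_lesion: float = 180.0
    tau_ligate: float = 600.0
    capture_radius_nm: float = 25.0

    def __post_init__(self) -> None:
        for name in ("tau_inhibit_on", "tau_inhibit_off", "tau_ku",
                     "tau_dnapk", "tau_phosphorylation", "tau_long_advance",
                     "tau_clean_per_lesion", "tau_ligate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_long_dissociate is not None and self.tau_long_dissociate <= 0:
            raise ValueError("tau_long_dissociate must be positive")
        if self.capture_radius_nm <= 0:
            raise ValueError("capture_radius must be positive")

    @property
    def dissociation_tau(self) -> float:
        return (self.tau_phosphorylation if self.tau_long_dissociate is None
                else self.tau_long_dissociate)


@dataclass
class DsbEnd:
    """One broken DNA end (mutable simulation record)."""

    end_id: int
    dsb_id: int
    position: np.ndarray
    state: StateEnum = StateEnum.NAKED
    lesions_remaining: int = 0
    k_steps: int = 0
    synapse_partner: int | None = None
    version: int = 0  # bumped to invalidate queued events


@dataclass(frozen=True)
class Join:
    end_a: int
    end_b: int
    time_s: float
    correct: bool


@dataclass(frozen=True)
class RepairOutcome:
    """Aggregated result of one repair run."""

    n_initial_dsbs: int
    joins: tuple
    residual_dsb_count: int
    misrepair_fraction_of_joined: float
    residual_fraction_of_total: float
    end_displacements: np.ndarray
    duration_s: float
    valid: bool = True  # False when the pattern was empty

    @property
    def n_joined(self) -> int:
        return len(self.joins)

    @property
    def n_misrepaired(self) -> int:
        return sum(1 for j in self.joins if not j.correct)

    def displacement_percentiles(self, qs=(50, 95)) -> dict:
        if self.end_displacements.size == 0:
            return {float(q): 0.0 for q in qs}
        return {float(q): float(np.percentile(self.end_displacements, q))
                for q in qs}


# event kinds
_MOTION, _TRANSITION, _RESOLVE, _LIGATE = range(4)


class RepairSimulation:
    """Priority-queue scheduler over motion and state-transition events.

    Exposed piecewise for testing: :meth:`step_motion`,
    :meth:`attempt_transitions`, :meth:`attempt_synapsis`,
    :meth:`resolve_synapse` and :meth:`clean_and_ligate` implement the
    individual mechanisms; :meth:`run` drives them to the configured
    duration.
    """

    def __init__(
        self,
        pattern: DamagePattern,
        duration_s: float = DAY_S,
        motion: MotionParams | None = None,
        kinetics: KineticConfig | None = None,
        seed: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.nucleus: Nucleus = pattern.nucleus
        self.duration = float(duration_s)
        self.motion = motion or MotionParams()
        self.kinetics = kinetics or KineticConfig()
        self.rng = rng if rng is not None else np.random.default_rng(seed)

        self.ends: list[DsbEnd] = []
        for dsb_id, dsb in enumerate(pattern.dsbs):
            pos = np.asarray(dsb.position_nm, dtype=float)
            split = int(self.rng.binomial(dsb.complexity, 0.5))
            for half, lesions in ((0, split), (1, dsb.complexity - split)):
                self.ends.append(
                    DsbEnd(end_id=2 * dsb_id + half, dsb_id=dsb_id,
                           position=pos.copy(), lesions_remaining=lesions)
                )
        self.initial_positions = (
            np.array([e.position for e in self.ends])
            if self.ends else np.empty((0, 3))
        )
        self.n_dsbs = len(pattern.dsbs)
        self.joins: list[Join] = []
        self.clock = 0.0
        self._heap: list = []
        self._seq = 0
        self._dnapk: set[int] = set()

        for end in self.ends:
            self._schedule_motion(end)
            self._schedule_transition(end)

    # -- scheduling helpers ------------------------------------------------

    def _push(self, time: float, kind: int, end_id: int, version: int,
              payload=None) -> None:
        if time > self.duration:
            return
        heapq.heappush(self._heap, (time, self._seq, kind, end_id, version, payload))
        self._seq += 1

    def _exp(self, tau: float) -> float:
        if math.isinf(tau):
            return math.inf
        return self.rng.exponential(tau)

    def _schedule_motion(self, end: DsbEnd) -> None:
        if self.motion.step_sigma == 0:
            return
        wait = self._exp(self.motion.wait_scale(end.k_steps))
        t = self.clock + wait
        if self.motion.duration_cap_s is not None and t > self.motion.duration_cap_s:
            return
        self._push(t, _MOTION, end.end_id, end.version)

    def _schedule_transition(self, end: DsbEnd) -> None:
        """Queue the next stochastic state change for a free end."""
        k = self.kinetics
        if end.state is StateEnum.NAKED:
            t_inh = self._exp(k.tau_inhibit_on)
            t_ku = self._exp(k.tau_ku)
            if t_ku == math.inf and t_inh == math.inf:
                return
            if t_ku <= t_inh:
                self._push(self.clock + t_ku, _TRANSITION, end.end_id,
                           end.version, StateEnum.KU)
            else:
                self._push(self.clock + t_inh, _TRANSITION, end.end_id,
                           end.version, StateEnum.INHIBITED)
        elif end.state is StateEnum.INHIBITED:
            self._push(self.clock + self._exp(k.tau_inhibit_off), _TRANSITION,
                       end.end_id, end.version, StateEnum.NAKED)
        elif end.state is StateEnum.KU:
            self._push(self.clock + self._exp(k.tau_dnapk), _TRANSITION,
                       end.end_id, end.version, StateEnum.DNAPK)
        # DNAPK has no timed transition: it waits for synapsis.

    # -- mechanisms --------------------------------------------------------

    def step_motion(self, end: DsbEnd) -> None:
        """Displace ``end`` by one CTRW jump with envelope rejection."""
        if end.state not in _MOBILE:
            return
        center = self.nucleus.center_nm
        r2 = self.nucleus.radius_nm**2
        for _ in range(10000):
            length = abs(self.rng.normal(0.0, self.motion.step_sigma))
            direction = self.rng.normal(size=3)
            norm = np.linalg.norm(direction)
            if norm < 1e-12:
                continue
            proposal = end.position + (length / norm) * direction
            if ((proposal - center) ** 2).sum() < r2:
                end.position = proposal
                break
        end.k_steps += 1
        self._schedule_motion(end)
        if end.state is StateEnum.DNAPK:
            self.attempt_synapsis(end)

    def attempt_transitions(self, end: DsbEnd, target: StateEnum) -> None:
        """Apply a queued state change and queue the follow-up."""
        allowed = {
            (StateEnum.NAKED, StateEnum.KU),
            (StateEnum.NAKED, StateEnum.INHIBITED),
            (StateEnum.INHIBITED, StateEnum.NAKED),
            (StateEnum.KU, StateEnum.DNAPK),
        }
        if (end.state, target) not in allowed:
            raise RuntimeError(
                f"illegal transition {end.state} -> {target} for end {end.end_id}"
            )
        end.state = target
        if target is StateEnum.DNAPK:
            self._dnapk.add(end.end_id)
            self.attempt_synapsis(end)
        else:
            self._schedule_transition(end)

    def attempt_synapsis(self, end: DsbEnd) -> bool:
        """Try to pair a DNA-PK-loaded end with one in capture range.

        Among all eligible partners within the capture radius one is chosen
        uniformly at random.  Both ends freeze at their midpoint as a
        long-range synaptic complex.
        """
        if end.state is not StateEnum.DNAPK:
            return False
        candidates = [
            i for i in self._dnapk
            if i != end.end_id and self.ends[i].synapse_partner is None
        ]
        if not candidates:
            return False
        pos = np.array([self.ends[i].position for i in candidates])
        d2 = ((pos - end.position) ** 2).sum(axis=1)
        in_range = np.flatnonzero(d2 <= self.kinetics.capture_radius_nm**2)
        if in_range.size == 0:
            return False
        partner = self.ends[candidates[int(self.rng.choice(in_range))]]
        self._form_synapse(end, partner)
        return True

    def _form_synapse(self, a: DsbEnd, b: DsbEnd) -> None:
        midpoint = 0.5 * (a.position + b.position)
        for e, other in ((a, b), (b, a)):
            e.position = midpoint.copy()
            e.state = StateEnum.LONG_SYNAPSE
            e.synapse_partner = other.end_id
            e.version += 1  # cancels queued motion/transition events
            self._dnapk.discard(e.end_id)
        t_dis = self._exp(self.kinetics.dissociation_tau)
        t_adv = self._exp(self.kinetics.tau_long_advance)
        first = min(a.end_id, b.end_id)
        if t_adv <= t_dis:
            self._push(self.clock + t_adv, _RESOLVE, first,
                       self.ends[first].version, "advance")
        else:
            self._push(self.clock + t_dis, _RESOLVE, first,
                       self.ends[first].version, "dissociate")

    def resolve_synapse(self, end: DsbEnd, outcome: str) -> None:
        """Dissolve a long-range complex or commit it to a short-range one."""
        if end.state is not StateEnum.LONG_SYNAPSE:  # pragma: no cover
            raise RuntimeError("resolve_synapse requires a LONG_SYNAPSE end")
        partner = self.ends[end.synapse_partner]
        if outcome == "dissociate":
            for e in (end, partner):
                e.state = StateEnum.NAKED
                e.synapse_partner = None
                e.version += 1
                self._schedule_motion(e)
                self._schedule_transition(e)
        else:  # advance: the pair is now irreversible
            for e in (end, partner):
                e.state = StateEnum.SHORT_SYNAPSE
                e.version += 1
            self.clean_and_ligate(end, partner)

    def clean_and_ligate(self, a: DsbEnd, b: DsbEnd) -> None:
        """Queue lesion cleaning and final ligation for a committed pair.

        Cleaning takes one exponential draw per remaining lesion across both
        ends; ligation one further exponential draw.
        """
        n_lesions = a.lesions_remaining + b.lesions_remaining
        t_clean = float(
            np.sum(self.rng.exponential(self.kinetics.tau_clean_per_lesion,
                                        size=n_lesions))
        )
        a.state = b.state = StateEnum.CLEANING
        t_done = self.clock + t_clean + self._exp(self.kinetics.tau_ligate)
        self._push(t_done, _LIGATE, min(a.end_id, b.end_id), a.version)

    def _ligate(self, end: DsbEnd) -> None:
        partner = self.ends[end.synapse_partner]
        for e in (end, partner):
            e.state = StateEnum.LIGATED
            e.lesions_remaining = 0
            e.version += 1
        self.joins.append(
            Join(end_a=end.end_id, end_b=partner.end_id, time_s=self.clock,
                 correct=end.dsb_id == partner.dsb_id)
        )

    # -- driver ------------------------------------------------------------

    def run(self) -> RepairOutcome:
        while self._heap:
            time, _, kind, end_id, version, payload = heapq.heappop(self._heap)
            end = self.ends[end_id]
            if version != end.version:
                continue  # stale event
            self.clock = time
            if kind == _MOTION:
                self.step_motion(end)
            elif kind == _TRANSITION:
                self.attempt_transitions(end, payload)
            elif kind == _RESOLVE:
                self.resolve_synapse(end, payload)
            elif kind == _LIGATE:
                self._ligate(end)
        self.clock = self.duration
        return self._outcome()

    def _outcome(self) -> RepairOutcome:
        if not self.ends:
            return RepairOutcome(
                n_initial_dsbs=0, joins=(), residual_dsb_count=0,
                misrepair_fraction_of_joined=0.0, residual_fraction_of_total=0.0,
                end_displacements=np.empty(0), duration_s=self.duration,
                valid=False,
            )
        final = np.array([e.position for e in self.ends])
        disp = np.sqrt(((final - self.initial_positions) ** 2).sum(axis=1))
        ligated = {e.dsb_id for e in self.ends} - {
            e.dsb_id for e in self.ends if e.state is not StateEnum.LIGATED
        }
        residual = self.n_dsbs - len(ligated)
        n_joined = len(self.joins)
        n_mis = sum(1 for j in self.joins if not j.correct)
        return RepairOutcome(
            n_initial_dsbs=self.n_dsbs,
            joins=tuple(self.joins),
            residual_dsb_count=residual,
            misrepair_fraction_of_joined=n_mis / n_joined if n_joined else 0.0,
            residual_fraction_of_total=residual / self.n_dsbs,
            end_displacements=disp,
            duration_s=self.duration,
        )


def run_repair(
    pattern: DamagePattern,
    duration_s: float = DAY_S,
    motion: MotionParams | None = None,
    kinetics: KineticConfig | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> RepairOutcome:
    """Simulate c-NHEJ repair of ``pattern`` and aggregate the outcome."""
    sim = RepairSimulation(pattern, duration_s=duration_s, motion=motion,
                           kinetics=kinetics, seed=seed, rng=rng)
    return sim.run()


def free_motion_msd(
    n_ends: int,
    sample_times_s,
    motion: MotionParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Ensemble MSD (nm²) of unconstrained ends at the given times.

    Vectorised CTRW without the nuclear envelope (ends start at the origin
    and never travel far enough to reach a micron-scale boundary); used to
    verify the sub-diffusive MSD exponent.
    """
    motion = motion or MotionParams()
    rng = np.random.default_rng(seed)
    times = np.asarray(sample_times_s, dtype=float)
    t_max = times.max()
    gamma = motion.aging_exponent
    # enough steps that the slowest walker passes t_max
    n_steps = int(((1 + gamma) * t_max / motion.wait_mean) ** (1 / (1 + gamma)) * 3) + 20
    scales = motion.wait_mean * (np.arange(n_steps) + 1.0) ** gamma
    waits = rng.exponential(scales, size=(n_ends, n_steps))
    event_times = np.cumsum(waits, axis=1)
    lengths = np.abs(rng.normal(0.0, motion.step_sigma, size=(n_ends, n_steps)))
    dirs = rng.normal(size=(n_ends, n_steps, 3))
    dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
    steps = lengths[..., None] * dirs
    paths = np.cumsum(steps, axis=1)
    msd = np.empty(times.size)
    for i, t in enumerate(times):
        idx = (event_times <= t).sum(axis=1)  # completed steps per end
        disp = np.where((idx > 0)[:, None],
                        paths[np.arange(n_ends), np.maximum(idx - 1, 0)], 0.0)
        msd[i] = float((disp**2).sum(axis=1).mean())
    return msd
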
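"""LET/dose correlations for misrepaired and residual DSB yields.

The repair-fidelity statistic of interest here is the *cluster density*: the
mean number of other double strand breaks (DSBs) within 70 nm of each DSB in
the initial damage pattern.  For protons and alpha particles the following
empirical correlations link beam quality (dose ``D`` in Gy, track-averaged
LET ``L`` in keV/µm) to the 24 h repair outcome:

.. math::

    F_{mis}  &= a \\cdot CD + b                       \\\\
    F_{res}  &= c                                     \\\\
    N_{DSB}  &= D (dL + e)                            \\\\
    CD(L)    &= f L^2 + g L + h                       \\\\
    \\text{Misrepair yield} &= N_{DSB} \\, F_{mis} \\, (1 - c) \\\\
    \\text{Residual yield}  &= N_{DSB} \\, c

with species-specific constants ``a``–``h`` shipped as package data.  The
fits hold on the clinically relevant LET range (roughly 0–20 keV/µm for the
DSB-yield linearity); evaluation outside that range is permitted but flagged.
Carbon ions are rejected: no calibrated constants exist for them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "CorrelationParams",
    "ValidityRange",
    "OutsideValidityRangeWarning",
    "load_params",
    "f_mis",
    "f_res",
    "n_dsb",
    "cluster_density_from_let",
    "misrepair_yield",
    "residual_yield",
    "crossover_let",
    "fit_params",
    "FitDiagnostics",
]

SUPPORTED_SPECIES = ("proton", "alpha")


class OutsideValidityRangeWarning(UserWarning):
    """Correlation evaluated outside the LET range it was fitted on."""


@dataclass(frozen=True)
class ValidityRange:
    """LET range (keV/µm) over which the yield linearity was fitted."""

    let_min: float = 0.0
    let_max: float = 20.0

    def __post_init__(self) -> None:
        if not self.let_min < self.let_max:
            raise ValueError("let_min must be < let_max")

    def contains(self, let: float) -> bool:
        return self.let_min <= let <= self.let_max


@dataclass(frozen=True)
class CorrelationParams:
    """Fitted constants a–h for one ion species.

    ``a``/``b``: slope and intercept of misrepair fraction vs cluster density;
    ``c``: constant residual fraction; ``d``/``e``: DSB yield per Gy vs LET;
    ``f``/``g``/``h``: quadratic cluster density vs LET.  ``stderr_percent``
    holds the asymptotic standard errors of the original fits (metadata only,
    never used in evaluation).
    """

    species: str
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    g: float
    h: float
    stderr_percent: dict = field(default_factory=dict)
    validity: ValidityRange = field(default_factory=ValidityRange)

    def __post_init__(self) -> None:
        if self.species not in SUPPORTED_SPECIES:
            raise ValueError(
                f"unsupported species {self.species!r}: calibrated "
                f"correlations exist only for {SUPPORTED_SPECIES}"
            )
        if not 0.0 < self.c < 1.0:
            raise ValueError("residual fraction c must lie in (0, 1)")
        if self.d <= 0 or self.e <= 0:
            raise ValueError("yield coefficients d, e must be positive")


def load_params(species: str) -> CorrelationParams:
    """Load the shipped default constants for ``species``."""
    if species not in SUPPORTED_SPECIES:
        raise ValueError(
            f"unsupported species {species!r}: calibrated correlations "
            f"exist only for {SUPPORTED_SPECIES}"
        )
    raw = json.loads(
        resources.files("nhejsim._data")
        .joinpath("correlation_params.json")
        .read_text()
    )[species]
    return CorrelationParams(
        species=species,
        a=raw["a"], b=raw["b"], c=raw["c"], d=raw["d"], e=raw["e"],
        f=raw["f"], g=raw["g"], h=raw["h"],
        stderr_percent=raw.get("stderr_percent", {}),
    )


def _check_let(let: float, params: CorrelationParams) -> None:
    if let < 0:
        raise ValueError("LET must be non-negative")
    if not params.validity.contains(let):
        warnings.warn(
            f"LET {let} keV/µm is outside the fitted validity range "
            f"[{params.validity.let_min}, {params.validity.let_max}]",
            OutsideValidityRangeWarning,
            stacklevel=3,
        )


def f_mis(cluster_density: float, params: CorrelationParams) -> float:
    """Misrepair fraction of joined DSBs predicted from cluster density."""
    if cluster_density < 0:
        raise ValueError("cluster density must be non-negative")
    value = params.a * cluster_density + params.b
    if not 0.0 <= value <= 1.0:
        warnings.warn(
            f"misrepair fraction {value:.4f} clamped to [0, 1]",
            UserWarning, stacklevel=2,
        )
        value = min(max(value, 0.0), 1.0)
    return value


def f_res(params: CorrelationParams) -> float:
    """Residual (unrepaired at 24 h) fraction of initial DSBs."""
    return params.c


def n_dsb(dose: float, let: float, params: CorrelationParams) -> float:
    """Expected initial DSB count for ``dose`` Gy at LET ``let`` keV/µm."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    _check_let(let, params)
    return dose * (params.d * let + params.e)


def cluster_density_from_let(let: float, params: CorrelationParams) -> float:
    """70 nm cluster density estimated from LET (dose independent)."""
    if let < 0:
        raise ValueError("LET must be non-negative")
    return params.f * let**2 + params.g * let + params.h


def misrepair_yield(dose: float, let: float, params: CorrelationParams) -> float:
    """Expected misrepaired DSBs per nucleus at 24 h."""
    cd = cluster_density_from_let(let, params)
    return n_dsb(dose, let, params) * f_mis(cd, params) * (1.0 - params.c)


def residual_yield(dose: float, let: float, params: CorrelationParams) -> float:
    """Expected residual (unrepaired) DSBs per nucleus at 24 h."""
    return n_dsb(dose, let, params) * params.c


def crossover_let(params: CorrelationParams) -> float | None:
    """LET above which misrepair yield exceeds residual yield.

    Dose cancels: the crossover solves
    ``a (f L² + g L + h) + b = c / (1 - c)``.  Returns the smallest positive
    root, or ``None`` if no positive root exists.
    """
    rhs = params.c / (1.0 - params.c)
    coeffs = (
        params.a * params.f,
        params.a * params.g,
        params.a * params.h + params.b - rhs,
    )
    if coeffs[0] == 0.0 and coeffs[1] == 0.0:
        return None
    roots = np.roots(coeffs)
    real = roots[np.isreal(roots)].real
    positive = np.sort(real[real > 0])
    return float(positive[0]) if positive.size else None


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit summaries returned by :func:`fit_params`."""

    r2_misrepair_vs_cd: float
    r2_yield_vs_let: float
    r2_cd_vs_let: float
    stderr: dict


def fit_params(grid, species: str) -> tuple[CorrelationParams, FitDiagnostics]:
    """Fit the correlation constants from a simulation grid.

    ``grid`` is an iterable of records with attributes or keys
    ``dose``, ``let``, ``cluster_density``, ``misrepair_fraction``,
    ``residual_fraction`` and ``dsb_count`` (one row per grid cell, values
    already averaged over repeats).  Least squares:

    * misrepair fraction vs cluster density  -> ``a`` (slope), ``b`` (intercept)
    * residual fraction                      -> ``c`` (constant fit = mean)
    * DSB count per Gy vs LET                -> ``d`` (slope), ``e`` (intercept)
    * cluster density vs LET                 -> ``f, g, h`` (quadratic)
    """

    def col(name: str) -> np.ndarray:
        out = []
        for row in grid:
            out.append(row[name] if isinstance(row, dict) else getattr(row, name))
        return np.asarray(out, dtype=float)

    let = col("let")
    if np.unique(let).size < 3:
        raise ValueError("need at least 3 distinct LET values to fit")
    dose = col("dose")
    cd = col("cluster_density")
    fmis = col("misrepair_fraction")
    fres = col("residual_fraction")
    ndsb = col("dsb_count")

    (a, b), r2_mis, se_ab = _polyfit_diag(cd, fmis, 1)
    c = float(np.mean(fres))
    se_c = float(np.std(fres, ddof=1) / np.sqrt(fres.size)) if fres.size > 1 else 0.0
    (d, e), r2_yield, se_de = _polyfit_diag(let, ndsb / dose, 1)
    (f, g, h), r2_cd, se_fgh = _polyfit_diag(let, cd, 2)

    stderr = {
        "a": se_ab[0], "b": se_ab[1], "c": se_c,
        "d": se_de[0], "e": se_de[1],
        "f": se_fgh[0], "g": se_fgh[1], "h": se_fgh[2],
    }
    params = CorrelationParams(
        species=species, a=float(a), b=float(b), c=c,
        d=float(d), e=float(e), f=float(f), g=float(g), h=float(h),
    )
    diag = FitDiagnostics(
        r2_misrepair_vs_cd=r2_mis,
        r2_yield_vs_let=r2_yield,
        r2_cd_vs_let=r2_cd,
        stderr=stderr,
    )
    return params, diag


def _polyfit_diag(x, y, deg):
    """Least-squares polynomial fit with R² and coefficient SEs."""
    design = np.vander(x, deg + 1)
    if np.linalg.matrix_rank(design) < deg + 1:
        raise ValueError("rank-deficient design: too few distinct x values")
    coef, res_ss, _, _ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ coef
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(y) - (deg + 1), 1)
    sigma2 = ss_res / dof
    try:
        cov = sigma2 * np.linalg.inv(design.T @ design)
        ses = list(np.sqrt(np.diag(cov)))
    except np.linalg.LinAlgError:  # pragma: no cover
        ses = [float("nan")] * (deg + 1)
    return coef, r2, ses
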
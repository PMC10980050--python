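"""Hydroxyl-radical footprinting (XFMS) dose-response analysis.

X-ray radiolysis of water hydroxylates solvent-accessible residues; the
fraction of a peptide left unmodified decays with exposure time. Each
site's dose-response is fitted to a single exponential
F(t) = exp(-k t) — fraction unmodified is 1 at zero dose by
construction, so no amplitude is fitted by default — giving a rate k in
1/s. Ratios of k between morphologies (tile in solution vs. in an
assembled shell) report relative changes in water accessibility, and are
correlated against simulation-derived per-residue metrics (SASA, water
residence time) for the matching exposed/buried monomer classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponse",
    "RateFit",
    "RatioComparison",
    "DEFAULT_EXPOSURES",
    "fit_dose_response",
    "k_ratio",
    "simulated_ratio",
    "correlate_ratios",
    "read_dose_responses",
]

#: X-ray exposure schedule (s) used throughout: 0 to 2000 s in 7 steps.
DEFAULT_EXPOSURES = np.array([0.0, 100.0, 250.0, 500.0, 750.0, 1000.0, 2000.0])


@dataclass(frozen=True)
class DoseResponse:
    """Fraction-unmodified vs. exposure for one residue label.

    Labels follow the reporting convention for unresolved sites:
    "M7" for a single residue, "M16,23" or "P77,P79,P88" for a group.
    """

    residue_label: str
    exposures: np.ndarray  # s, strictly increasing, >= 0
    fraction_unmodified: np.ndarray  # in [0, 1]
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        exp = np.asarray(self.exposures, dtype=float)
        frac = np.asarray(self.fraction_unmodified, dtype=float)
        if len(exp) != len(frac):
            raise ValueError("exposures and fractions must have equal length")
        if np.any(np.diff(exp) <= 0) or np.any(exp < 0):
            raise ValueError("exposures must be non-negative, strictly increasing")
        if np.any((frac < 0) | (frac > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        object.__setattr__(self, "exposures", exp)
        object.__setattr__(self, "fraction_unmodified", frac)


@dataclass(frozen=True)
class RateFit:
    """Fitted hydroxylation rate for one site."""

    residue_label: str
    k: float  # 1/s
    k_se: float  # 1/s
    n_points: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.k < 0 or self.k_se < 0:
            raise ValueError("k and k_se must be >= 0")


def _loglinear_k(exposures: np.ndarray, fractions: np.ndarray) -> float:
    """Slope-based initial estimate from ln F on strictly positive points."""
    pos = fractions > 0
    if pos.sum() < 2:
        return 0.0
    t, y = exposures[pos], np.log(fractions[pos])
    slope = np.polyfit(t, y, 1)[0]
    return max(-slope, 0.0)


def fit_dose_response(dr: DoseResponse, fit_amplitude: bool = False) -> RateFit:
    """Nonlinear least-squares single-exponential fit F(t) = exp(-k t).

    The initial k comes from log-linear regression on the strictly
    positive fractions; the standard error from the fit covariance.
    With ``fit_amplitude`` the model becomes A*exp(-k t) (off by
    default: fraction unmodified is 1 at zero dose by construction).
    """
    t = dr.exposures
    y = dr.fraction_unmodified
    if len(t) < 3:
        raise ValueError("need at least 3 exposure points")
    if np.allclose(y, 1.0):
        return RateFit(dr.residue_label, 0.0, 0.0, len(t), True)
    k0 = _loglinear_k(t, y)
    sigma = dr.sd if dr.sd is not None else None
    try:
        if fit_amplitude:
            popt, pcov = optimize.curve_fit(
                lambda tt, k, a: a * np.exp(-k * tt),
                t, y, p0=[max(k0, 1e-12), 1.0],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                sigma=sigma, maxfev=10000,
            )
        else:
            popt, pcov = optimize.curve_fit(
                lambda tt, k: np.exp(-k * tt),
                t, y, p0=[max(k0, 1e-12)],
                bounds=(0.0, np.inf),
                sigma=sigma, maxfev=10000,
            )
        k = float(popt[0])
        k_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
        return RateFit(dr.residue_label, k, k_se, len(t), True)
    except RuntimeError:
        return RateFit(dr.residue_label, k0, 0.0, len(t), False)


def k_ratio(k_solution: RateFit, k_shell: RateFit) -> tuple[float, float]:
    """Solution/shell rate ratio with first-order error propagation.

    ratio = k_sol / k_shell;
    se = ratio * sqrt((se_sol/k_sol)^2 + (se_shell/k_shell)^2).
    """
    if k_shell.k == 0:
        raise ZeroDivisionError(
            f"shell rate for {k_shell.residue_label!r} is zero; ratio undefined"
        )
    ratio = k_solution.k / k_shell.k
    if k_solution.k == 0:
        return ratio, 0.0
    rel = np.sqrt(
        (k_solution.k_se / k_solution.k) ** 2 + (k_shell.k_se / k_shell.k) ** 2
    )
    return ratio, ratio * rel


def _label_residue_ids(label: str) -> list[int]:
    """Residue numbers from a label like "M7", "M16,23" or "P77,P79,P88"."""
    ids = []
    for part in label.split(","):
        digits = "".join(ch for ch in part if ch.isdigit())
        if not digits:
            raise ValueError(f"cannot parse residue label part {part!r}")
        ids.append(int(digits))
    return ids


def simulated_ratio(
    metric_exposed: pd.DataFrame,
    metric_buried: pd.DataFrame,
    residue_labels: Iterable[str],
    value_column: str | None = None,
) -> dict[str, float]:
    """Exposed/buried metric ratios at labeled residues.

    Both tables must be keyed by ``residue_id`` (e.g. the outputs of
    :func:`bmcshell.metrics.sasa_trajectory_mean` or
    :func:`bmcshell.hydration.mean_residence`). Multi-residue labels
    average the metric over the listed residues before taking the ratio.
    A zero buried value yields NaN (flagged undefined).
    """
    def col(df: pd.DataFrame) -> str:
        if value_column is not None:
            return value_column
        candidates = [
            c for c in df.columns
            if c not in ("residue_id", "residue_name", "class", "chain_id")
            and np.issubdtype(df[c].dtype, np.number)
        ]
        return candidates[0]

    exp_map = dict(zip(metric_exposed["residue_id"], metric_exposed[col(metric_exposed)]))
    bur_map = dict(zip(metric_buried["residue_id"], metric_buried[col(metric_buried)]))
    out: dict[str, float] = {}
    for label in residue_labels:
        rids = _label_residue_ids(label)
        missing = [r for r in rids if r not in exp_map or r not in bur_map]
        if missing:
            raise KeyError(f"label {label!r}: residues {missing} missing from tables")
        e = float(np.mean([exp_map[r] for r in rids]))
        b = float(np.mean([bur_map[r] for r in rids]))
        out[label] = e / b if b != 0 else float("nan")
    return out


@dataclass
class RatioComparison:
    """Experimental vs. simulated ratio pairs with an OLS summary."""

    rows: pd.DataFrame  # columns: residue_label, experimental, simulated
    slope: float
    intercept: float
    pearson_r: float
    excluded: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not np.isnan(self.pearson_r) and abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|pearson_r| must be <= 1")


def correlate_ratios(
    experimental: Mapping[str, float],
    simulated: Mapping[str, float],
    exclude: Iterable[str] = (),
) -> RatioComparison:
    """OLS line of simulated on experimental ratios plus Pearson r.

    Labels in ``exclude`` are dropped before fitting (the set is recorded
    in the result); at least 3 shared labels must remain.
    """
    excl = set(exclude)
    labels = [
        lab for lab in experimental
        if lab in simulated and lab not in excl
        and np.isfinite(experimental[lab]) and np.isfinite(simulated[lab])
    ]
    if len(labels) < 3:
        raise ValueError(
            f"need >= 3 shared labels after exclusion; have {len(labels)}"
        )
    x = np.array([experimental[lab] for lab in labels])
    y = np.array([simulated[lab] for lab in labels])
    res = stats.linregress(x, y)
    rows = pd.DataFrame(
        {"residue_label": labels, "experimental": x, "simulated": y}
    )
    return RatioComparison(
        rows=rows,
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        excluded=tuple(sorted(excl)),
    )


def read_dose_responses(path: str | Path) -> dict[str, DoseResponse]:
    """Read dose-response curves from a CSV/TSV table.

    Expected columns: residue_label, exposure_s, fraction_unmodified
    and optionally sd; separator inferred from the extension.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    out: dict[str, DoseResponse] = {}
    for label, grp in df.groupby("residue_label", sort=False):
        grp = grp.sort_values("exposure_s")
        out[str(label)] = DoseResponse(
            residue_label=str(label),
            exposures=grp["exposure_s"].to_numpy(float),
            fraction_unmodified=grp["fraction_unmodified"].to_numpy(float),
            sd=grp["sd"].to_numpy(float) if "sd" in grp else None,
        )
    return out
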
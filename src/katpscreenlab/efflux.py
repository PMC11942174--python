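"""Rb+ efflux assay quantification and variable-slope Hill inhibition fitting.

The Rb+ efflux assay reads out K_ATP channel activity in intact cells:
cells preloaded with Rb+ release it through open channels, and the
fractional efflux is the Rb+ in the efflux solution divided by total Rb+
(efflux + cell lysate). This module converts raw plate readings into
background-subtracted, normalized fractional-efflux tables, fits the
four-parameter logistic inhibition model

    y(x) = bottom + (top - bottom) / (1 + (x / IC50)^h),   h > 0,

("log(inhibitor) vs response, variable slope") to dose-response data, and
summarizes IC50s across biological replicates as mean +/- SEM. A thin
one-way-ANOVA + Dunnett/Tukey comparison against a control group is also
provided.

Doses are in µM throughout; dose 0 denotes vehicle. Vehicle points cannot
enter a log-dose axis, but the four-parameter model evaluates naturally at
x = 0 (to ``top``), so they anchor the top plateau during fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "WELL_COLUMNS",
    "FractionalEffluxTable",
    "HillFitResult",
    "Ic50Summary",
    "hill_curve",
    "fractional_efflux",
    "preprocess",
    "fit_hill",
    "ic50_with_sem",
    "compare_to_control",
]

#: Plate schema shared with the synthetic generator and CSV I/O.
WELL_COLUMNS = [
    "condition",
    "dose_uM",
    "technical_rep",
    "biological_rep",
    "efflux_signal",
    "lysate_signal",
    "is_untransfected",
]


def hill_curve(
    x: np.ndarray | float, top: float, bottom: float, ic50: float, slope: float
) -> np.ndarray | float:
    """Four-parameter logistic inhibition curve; decreasing in dose for slope > 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / ic50) ** slope, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fractional_efflux(efflux_signal, lysate_signal):
    """Fraction of Rb+ released: efflux / (efflux + lysate), in [0, 1].

    Raises if any well has both signals zero (no Rb+ measured at all).
    """
    e = np.asarray(efflux_signal, dtype=float)
    l = np.asarray(lysate_signal, dtype=float)
    if np.any(e < 0) or np.any(l < 0):
        raise ValueError("signals must be non-negative")
    total = e + l
    bad = np.atleast_1d(total == 0)
    if bad.any():
        idx = np.flatnonzero(bad)
        raise ValueError(
            f"wells with zero total Rb+ signal at positions {idx.tolist()}"
        )
    return e / total


@dataclass
class FractionalEffluxTable:
    """Per (condition, dose, biological replicate) fractional efflux.

    ``data`` has columns condition, dose_uM, biological_rep, fraction,
    clipped; transforms applied are recorded in ``provenance``. A processed
    table refuses re-processing (the pipeline is not idempotent past the
    normalization step, so silent double application is an error).
    """

    data: pd.DataFrame
    provenance: list[str] = field(default_factory=list)
    background: float = 0.0
    reference_condition: str = ""

    @property
    def processed(self) -> bool:
        return "normalized" in self.provenance


def preprocess(
    wells: pd.DataFrame, reference_condition: str
) -> FractionalEffluxTable:
    """Raw plate wells -> averaged, background-subtracted, normalized fractions.

    Per biological replicate: technical duplicates are averaged, the mean
    untransfected fraction is subtracted, and the result is divided by the
    mean fraction of ``reference_condition`` wells at dose 0 (vehicle).
    Negative post-subtraction fractions are clipped to 0 and flagged, never
    silently.
    """
    if isinstance(wells, FractionalEffluxTable):
        raise ValueError(
            "input is already a processed FractionalEffluxTable; "
            "preprocessing is refused on second application"
        )
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ValueError(f"plate table lacks columns {missing}")
    df = wells.copy()
    df["fraction"] = fractional_efflux(df["efflux_signal"], df["lysate_signal"])

    # average technical duplicates within (condition, dose, biological rep)
    grouped = (
        df.groupby(
            ["condition", "dose_uM", "biological_rep", "is_untransfected"],
            as_index=False,
        )["fraction"]
        .mean()
    )

    ut = grouped[grouped["is_untransfected"]]
    if ut.empty:
        raise ValueError("no untransfected wells present (background group missing)")
    background = float(ut["fraction"].mean())

    sample = grouped[~grouped["is_untransfected"]].copy()
    ref = sample[
        (sample["condition"] == reference_condition) & (sample["dose_uM"] == 0)
    ]
    if ref.empty:
        raise ValueError(
            f"no vehicle (dose 0) wells for reference condition "
            f"{reference_condition!r}"
        )

    sample["fraction"] = sample["fraction"] - background
    sample["clipped"] = sample["fraction"] < 0
    sample.loc[sample["clipped"], "fraction"] = 0.0
    ref_mean = float(
        sample.loc[
            (sample["condition"] == reference_condition) & (sample["dose_uM"] == 0),
            "fraction",
        ].mean()
    )
    if ref_mean <= 0:
        raise ValueError("reference condition has non-positive mean fraction")
    sample["fraction"] = sample["fraction"] / ref_mean

    out = sample[["condition", "dose_uM", "biological_rep", "fraction", "clipped"]]
    return FractionalEffluxTable(
        data=out.reset_index(drop=True),
        provenance=["technical_averaged", "background_subtracted", "normalized"],
        background=background,
        reference_condition=reference_condition,
    )


@dataclass
class HillFitResult:
    """Fitted four-parameter inhibition curve with covariance-based SEs."""

    top: float
    bottom: float
    ic50: float
    slope: float
    se_ic50: float
    se_slope: float
    n_points: int
    converged: bool
    residual_sse: float

    def predict(self, x):
        return hill_curve(x, self.top, self.bottom, self.ic50, self.slope)


def _hill_log(x, top, bottom, log10_ic50, slope):
    return hill_curve(x, top, bottom, 10.0**log10_ic50, slope)


def fit_hill(
    doses: Sequence[float],
    responses: Sequence[float],
    weights: Sequence[float] | None = None,
) -> HillFitResult:
    """Least-squares fit of the variable-slope inhibition curve.

    Requires >= 4 distinct nonzero doses. The IC50 is fitted on a log10
    scale with multi-start from 5 log-spaced seeds spanning the dose range;
    bounds are top in [0, 1.5], bottom in [0, 1.5] (bottom > top flags
    non-convergence), slope in (0, 10]. A fit whose IC50 falls outside
    [min dose / 100, max dose * 100] or whose response range is degenerate
    is reported with ``converged=False`` rather than raised.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("doses and responses must have equal length")
    pos = x[x > 0]
    if len(np.unique(pos)) < 4:
        raise ValueError("need at least 4 distinct nonzero doses")
    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        sigma = 1.0 / np.sqrt(w)

    lo_ic, hi_ic = pos.min(), pos.max()
    llo, lhi = math.log10(lo_ic) - 2, math.log10(hi_ic) + 2
    bounds = ([0.0, 0.0, llo, 1e-3], [1.5, 1.5, lhi, 10.0])
    top0 = float(np.clip(y.max(), 0.05, 1.5))
    bot0 = float(np.clip(y.min(), 0.0, 1.45))

    best = None
    for lic0 in np.linspace(math.log10(lo_ic), math.log10(hi_ic), 5):
        p0 = [top0, bot0, lic0, 1.0]
        try:
            popt, pcov = optimize.curve_fit(
                _hill_log, x, y, p0=p0, sigma=sigma, bounds=bounds,
                maxfev=5000, xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - _hill_log(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)

    if best is None:
        return HillFitResult(
            float("nan"), float("nan"), float("nan"), float("nan"),
            float("nan"), float("nan"), len(x), False, float("nan"),
        )
    sse, popt, pcov = best
    top, bottom, lic, slope = (float(v) for v in popt)
    ic50 = 10.0**lic
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    se_ic50 = float(math.log(10.0) * ic50 * perr[2])
    se_slope = float(perr[3])

    flat = float(np.ptp(y)) < 1e-4 or abs(top - bottom) < 1e-4
    in_range = lo_ic / 100.0 <= ic50 <= hi_ic * 100.0
    converged = (not flat) and in_range and bottom <= top
    return HillFitResult(
        top, bottom, ic50, slope, se_ic50, se_slope, len(x), converged, sse
    )


@dataclass
class Ic50Summary:
    """IC50 mean and SEM across biological replicates, with per-replicate fits."""

    mean_ic50: float
    sem_ic50: float
    n_replicates: int
    fits: list[HillFitResult]
    excluded: list[int]


def ic50_with_sem(
    replicates: Sequence[tuple[Sequence[float], Sequence[float]]],
) -> Ic50Summary:
    """Per-replicate Hill fits summarized as mean IC50 +/- SEM.

    Non-convergent replicates are excluded with a warning; fewer than two
    convergent replicates is an error (an SEM then has no meaning).
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 biological replicates")
    fits, values, excluded = [], [], []
    for i, (d, r) in enumerate(replicates):
        fit = fit_hill(d, r)
        fits.append(fit)
        if fit.converged:
            values.append(fit.ic50)
        else:
            excluded.append(i)
    if excluded:
        import warnings

        warnings.warn(
            f"excluded non-convergent replicates {excluded}", stacklevel=2
        )
    if len(values) < 2:
        raise ValueError("fewer than 2 convergent replicate fits")
    arr = np.asarray(values)
    return Ic50Summary(
        mean_ic50=float(arr.mean()),
        sem_ic50=float(arr.std(ddof=1) / math.sqrt(len(arr))),
        n_replicates=len(arr),
        fits=fits,
        excluded=excluded,
    )


def compare_to_control(
    groups: Mapping[str, Sequence[float]],
    control: str,
    method: str = "dunnett",
) -> dict:
    """One-way ANOVA plus Dunnett (vs control) or Tukey (all pairs) post hoc.

    Returns the ANOVA F and p plus a table of per-group mean effects
    (difference from control) and adjusted p-values. Groups of identical
    constants (zero variance everywhere) are flagged, with all adjusted
    p-values set to 1 by convention.
    """
    if method not in ("dunnett", "tukey"):
        raise ValueError(f"unknown method {method!r}")
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    others = [k for k in arrays if k != control]
    ctrl = arrays[control]
    effects = {k: float(arrays[k].mean() - ctrl.mean()) for k in others}

    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0.0:
        return {
            "anova_F": float("nan"),
            "anova_p": float("nan"),
            "degenerate": True,
            "comparisons": pd.DataFrame(
                {"group": others, "effect": [0.0] * len(others),
                 "p_adj": [1.0] * len(others)}
            ),
        }

    F, p = stats.f_oneway(*arrays.values())
    if method == "dunnett":
        res = stats.dunnett(*(arrays[k] for k in others), control=ctrl)
        p_adj = list(np.atleast_1d(res.pvalue).astype(float))
        table = pd.DataFrame(
            {"group": others, "effect": [effects[k] for k in others], "p_adj": p_adj}
        )
    else:
        res = stats.tukey_hsd(*(arrays[k] for k in arrays))
        keys = list(arrays)
        rows = []
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                rows.append(
                    {
                        "group": f"{keys[i]} vs {keys[j]}",
                        "effect": float(arrays[keys[i]].mean() - arrays[keys[j]].mean()),
                        "p_adj": float(res.pvalue[i, j]),
                    }
                )
        table = pd.DataFrame(rows)
    return {
        "anova_F": float(F),
        "anova_p": float(p),
        "degenerate": False,
        "comparisons": table,
    }
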
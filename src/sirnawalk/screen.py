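"""Plate normalization, allele-discrimination statistics and screen simulation.

Plates are long-form :class:`pandas.DataFrame` tables with one row per
channel reading::

    well_id  construct_id  target  channel  group  value

``target`` is the allele of the co-transfected reporter (``wt``/``mut``),
``channel`` the reporter read (``renilla``/``firefly`` for dual-luciferase,
``eGFP``/``mCherry`` for dual-fluorescence), ``group`` one of
``experimental``, ``nonspecific_control``, ``background``.

Normalization follows the two assay conventions:

* dual-luciferase — per-well Renilla:firefly ratio, divided by the mean
  control ratio for the same target allele;
* fluorescence — per-channel background subtraction (floored at zero),
  divided by the mean background-subtracted control signal.

Discrimination statistics per construct: normalized expression of each
allele, percent silencing (``100 * (1 - rel)``), fold discrimination
(``wt_rel / mut_rel``; > 1 means mutant-selective), silencing difference in
percentage points, and an unpaired two-tailed t-test p-value. No
multiple-testing correction is applied by default; raw p-values are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLATE_COLUMNS",
    "DiscriminationResult",
    "normalize_luciferase",
    "normalize_fluorescence",
    "ttest_unpaired_two_tailed",
    "discrimination",
    "screen_discrimination",
    "simulate_screen",
]

PLATE_COLUMNS = ["well_id", "construct_id", "target", "channel", "group", "value"]


def _check_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate is missing columns {missing}")
    if (plate["value"] < 0).any():
        raise ValueError("raw plate values must be non-negative")
    return plate


def normalize_luciferase(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-well Renilla:firefly ratios normalized to the target's control mean.

    Returns one row per well: ``construct_id, target, well_id, group, ratio,
    norm_value``. Control wells are themselves normalized against their own
    mean, so each control group averages exactly 1.0.
    """
    plate = _check_plate(plate)
    wide = plate.pivot_table(
        index=["well_id", "construct_id", "target", "group"],
        columns="channel",
        values="value",
        aggfunc="first",
    ).reset_index()
    for ch in ("renilla", "firefly"):
        if ch not in wide.columns or wide[ch].isna().any():
            raise ValueError(f"every well needs a paired {ch} reading")
    if (wide["firefly"] == 0).any():
        bad = wide.loc[wide["firefly"] == 0, "well_id"].tolist()
        raise ValueError(f"firefly reading of zero in wells {bad}")
    wide["ratio"] = wide["renilla"] / wide["firefly"]

    out = []
    for target, sub in wide.groupby("target"):
        ctrl = sub[sub["group"] == "nonspecific_control"]
        if ctrl.empty:
            raise ValueError(f"no nonspecific_control wells for target {target!r}")
        ctrl_mean = ctrl["ratio"].mean()
        sub = sub.copy()
        sub["norm_value"] = sub["ratio"] / ctrl_mean
        out.append(sub)
    cols = ["construct_id", "target", "well_id", "group", "ratio", "norm_value"]
    return pd.concat(out, ignore_index=True)[cols]


def normalize_fluorescence(plate: pd.DataFrame) -> pd.DataFrame:
    """Background-subtracted fluorescence normalized to the channel's control.

    Channels are handled independently: for each ``(target, channel)`` the
    mean of the ``background`` wells (target alone) is subtracted from every
    reading, negative values are floored at zero, and experimental wells are
    divided by the mean background-subtracted ``nonspecific_control`` signal.
    """
    plate = _check_plate(plate)
    out = []
    for (target, channel), sub in plate.groupby(["target", "channel"]):
        bg = sub[sub["group"] == "background"]
        if bg.empty:
            raise ValueError(f"no background wells for target {target!r} channel {channel!r}")
        ctrl = sub[sub["group"] == "nonspecific_control"]
        if ctrl.empty:
            raise ValueError(
                f"no nonspecific_control wells for target {target!r} channel {channel!r}"
            )
        bg_mean = bg["value"].mean()
        sub = sub[sub["group"] != "background"].copy()
        sub["bg_subtracted"] = (sub["value"] - bg_mean).clip(lower=0.0)
        ctrl_mean = (ctrl["value"] - bg_mean).clip(lower=0.0).mean()
        if ctrl_mean <= 0:
            raise ValueError(
                f"control mean does not exceed background for target {target!r} "
                f"channel {channel!r}"
            )
        sub["norm_value"] = sub["bg_subtracted"] / ctrl_mean
        out.append(sub)
    cols = ["construct_id", "target", "well_id", "group", "channel", "bg_subtracted", "norm_value"]
    return pd.concat(out, ignore_index=True)[cols]


def ttest_unpaired_two_tailed(
    group_a, group_b, equal_variance: bool = True
) -> tuple[float, float, float]:
    """Classical two-sample t-test; returns ``(t, df, p)``.

    Two identical constant groups give ``p = 1.0`` by convention; constant
    groups with different means have no defined t statistic and raise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    if equal_variance:
        df = float(a.size + b.size - 2)
    else:
        df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


@dataclass(frozen=True)
class DiscriminationResult:
    """Allele-discrimination summary for one construct."""

    construct_id: str
    wt_rel: float
    mut_rel: float
    wt_silencing: float  # percent
    mut_silencing: float  # percent
    fold_discrimination: float  # wt_rel / mut_rel; inf when mut_rel == 0
    silencing_difference: float  # percentage points, mut - wt
    p_value: float
    wt_sd: float
    mut_sd: float
    n_wt: int
    n_mut: int
    infinite_fold: bool = False

    def report(self) -> dict:
        """Rounded view: percentages to 0 dp, folds and p to standard style."""
        return {
            "construct_id": self.construct_id,
            "wt_silencing_pct": round(self.wt_silencing),
            "mut_silencing_pct": round(self.mut_silencing),
            "fold_discrimination": (
                math.inf if self.infinite_fold else round(self.fold_discrimination, 2)
            ),
            "silencing_difference_pct_points": round(self.silencing_difference),
            "p_value": self.p_value,
        }


def discrimination(
    wt_values,
    mut_values,
    construct_id: str = "",
    equal_variance: bool = True,
) -> DiscriminationResult:
    """Compute discrimination statistics from normalized replicate groups.

    ``wt_values`` / ``mut_values`` are the per-replicate normalized
    expressions of the wild-type and mutant targets under one construct
    (nonspecific control = 1). The p-value is the unpaired two-tailed t-test
    comparing the two groups; see docs/methods.md for the calibration caveat
    when both groups were scaled by noisy control estimates.
    """
    wt = np.asarray(wt_values, dtype=float)
    mut = np.asarray(mut_values, dtype=float)
    wt_rel = float(wt.mean())
    mut_rel = float(mut.mean())
    if mut_rel < 0 or wt_rel < 0:
        raise ValueError("normalized expression must be non-negative")
    infinite = mut_rel == 0
    fold = math.inf if infinite else wt_rel / mut_rel
    wt_sil = 100.0 * (1.0 - wt_rel)
    mut_sil = 100.0 * (1.0 - mut_rel)
    try:
        _, _, p = ttest_unpaired_two_tailed(wt, mut, equal_variance=equal_variance)
    except ValueError:
        # degenerate noiseless groups with unequal means: no defined t statistic
        p = float("nan")
    return DiscriminationResult(
        construct_id=construct_id,
        wt_rel=wt_rel,
        mut_rel=mut_rel,
        wt_silencing=wt_sil,
        mut_silencing=mut_sil,
        fold_discrimination=fold,
        silencing_difference=mut_sil - wt_sil,
        p_value=p,
        wt_sd=float(wt.std(ddof=1)) if wt.size > 1 else 0.0,
        mut_sd=float(mut.std(ddof=1)) if mut.size > 1 else 0.0,
        n_wt=int(wt.size),
        n_mut=int(mut.size),
        infinite_fold=infinite,
    )


def screen_discrimination(
    plate: pd.DataFrame, mode: str = "luciferase", equal_variance: bool = True
) -> dict[str, DiscriminationResult]:
    """Normalize a plate and score every experimental construct on it."""
    if mode == "luciferase":
        norm = normalize_luciferase(plate)
    elif mode == "fluorescence":
        norm = normalize_fluorescence(plate)
    else:
        raise ValueError(f"mode must be 'luciferase' or 'fluorescence', got {mode!r}")
    exp = norm[norm["group"] == "experimental"]
    results = {}
    for cid, sub in exp.groupby("construct_id"):
        wt = sub.loc[sub["target"] == "wt", "norm_value"].to_numpy()
        mut = sub.loc[sub["target"] == "mut", "norm_value"].to_numpy()
        if wt.size < 2 or mut.size < 2:
            raise ValueError(
                f"construct {cid!r} needs >= 2 replicate wells per allele "
                f"(got wt={wt.size}, mut={mut.size})"
            )
        results[str(cid)] = discrimination(
            wt, mut, construct_id=str(cid), equal_variance=equal_variance
        )
    return results


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise at coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_screen(
    true_wt_rel: float,
    true_mut_rel: float,
    mode: str = "luciferase",
    n: int = 6,
    cv: float = 0.10,
    seed: int | np.random.Generator = 0,
    construct_id: str = "construct",
    renilla_baseline: float = 5e4,
    firefly_baseline: float = 1e5,
    background_level: float = 100.0,
    signal_level: float = 1000.0,
) -> pd.DataFrame:
    """Generate a synthetic plate around known true relative expressions.

    Every reading carries independent multiplicative log-normal noise at the
    given CV. The plate contains ``n`` experimental wells per target allele,
    ``n`` nonspecific-control wells per target and (fluorescence mode) ``n``
    background wells per target, mirroring the replicate structure of a
    six-replicate reporter screen. Reproducible for a given seed.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    for name, v in (("true_wt_rel", true_wt_rel), ("true_mut_rel", true_mut_rel)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows: list[tuple] = []
    channel_of = {"wt": "eGFP", "mut": "mCherry"}

    if mode == "luciferase":
        for target in ("wt", "mut"):
            rel = true_wt_rel if target == "wt" else true_mut_rel
            for group, level in (("experimental", rel), ("nonspecific_control", 1.0)):
                cid = construct_id if group == "experimental" else "nonspecific"
                ren = renilla_baseline * level * _noise(rng, cv, n)
                fir = firefly_baseline * _noise(rng, cv, n)
                for i in range(n):
                    wid = f"{target}_{group}_{i + 1}"
                    rows.append((wid, cid, target, "renilla", group, ren[i]))
                    rows.append((wid, cid, target, "firefly", group, fir[i]))
    elif mode == "fluorescence":
        for target in ("wt", "mut"):
            rel = true_wt_rel if target == "wt" else true_mut_rel
            ch = channel_of[target]
            specs = (
                ("experimental", construct_id, rel),
                ("nonspecific_control", "nonspecific", 1.0),
                ("background", "target_alone", None),
            )
            for group, cid, level in specs:
                bg = background_level * _noise(rng, cv, n)
                if level is None:
                    vals = bg
                else:
                    vals = bg + signal_level * level * _noise(rng, cv, n)
                for i in range(n):
                    wid = f"{target}_{group}_{i + 1}"
                    rows.append((wid, cid, target, ch, group, vals[i]))
    else:
        raise ValueError(f"mode must be 'luciferase' or 'fluorescence', got {mode!r}")

    return pd.DataFrame(rows, columns=PLATE_COLUMNS)
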
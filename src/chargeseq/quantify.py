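"""Charging estimators and group statistics.

Two estimators of the charged fraction are implemented:

* the sequencing-based **charge ratio** — the spike-in-normalized read
  abundance of an isodecoder in the periodate-oxidized (charged-only)
  library divided by that in the untreated control (total) library; and
* the qPCR **charged fraction** — within each sample the spike Ct is
  subtracted from the target Ct (delta-Ct), and the fraction is
  base^(dCt_nonox - dCt_ox), the delta-delta-Ct fold change between the
  total and the charged template.

Both are clamped to [0, 1]; the raw ratio is preserved.  Isodecoders with
fewer control reads than ``min_control_reads`` are reported absent with a
``low_coverage`` flag (the rule that excluded a poorly covered Ile-GAT
isodecoder from whole-compartment profiling).  Group comparisons cover the
two designs used with these measurements: a paired two-group t test and
one-way ANOVA followed by Holm-Sidak-adjusted pairwise comparisons.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assign import AssignmentCounts
from .simulate import NON_OXIDIZED, OXIDIZED

DEFAULT_MIN_CONTROL_READS = 100
DEFAULT_SPIKE_FLOOR = 100


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class ChargeRatio:
    isodecoder: str
    raw_ratio: float | None
    charge_ratio: float | None
    control_count: int
    flags: frozenset[str]


def compute_charge_ratios(
    oxidized: AssignmentCounts,
    control: AssignmentCounts,
    min_control_reads: int = DEFAULT_MIN_CONTROL_READS,
    spike_floor: int = DEFAULT_SPIKE_FLOOR,
) -> pd.DataFrame:
    """Per-isodecoder charge ratios from an oxidized/control library pair.

    Each isodecoder count is divided by its own library's spike-in count
    (the spike is a fixed-mass internal standard, absorbing both depth and
    ligation-efficiency differences); library size is kept as a QC
    covariate and a warning is emitted when the spike and library-size
    scale factors disagree by more than 3-fold.  Ratios above 1 are clamped
    with a ``clamped`` flag; isodecoders under ``min_control_reads`` in the
    control library are reported absent with ``low_coverage``.
    """
    for name, counts in (("oxidized", oxidized), ("control", control)):
        if counts.spike_in < spike_floor:
            raise QuantError(
                f"{name} library spike-in count {counts.spike_in} below floor "
                f"{spike_floor}; cannot normalize"
            )
    spike_factor = oxidized.spike_in / control.spike_in
    size_factor = oxidized.library_size / control.library_size
    if spike_factor / size_factor > 3 or size_factor / spike_factor > 3:
        warnings.warn(
            "spike-in and library-size scale factors disagree by >3-fold "
            f"({spike_factor:.3g} vs {size_factor:.3g}); check spike input",
            stacklevel=2,
        )

    keys = sorted(set(oxidized.isodecoder_counts) | set(control.isodecoder_counts))
    rows = []
    for key in keys:
        ox = oxidized.isodecoder_counts.get(key, 0)
        ct = control.isodecoder_counts.get(key, 0)
        flags: set[str] = set()
        if ct < min_control_reads:
            flags.add("low_coverage")
            raw = ratio = None
        else:
            raw = (ox / oxidized.spike_in) / (ct / control.spike_in)
            ratio = raw
            if ratio > 1.0:
                ratio = 1.0
                flags.add("clamped")
        rows.append(
            {
                "isodecoder": key,
                "raw_ratio": raw,
                "charge_ratio": ratio,
                "oxidized_count": ox,
                "control_count": ct,
                "flags": ",".join(sorted(flags)),
            }
        )
    return pd.DataFrame(rows)


def qpcr_charged_fraction(
    records: pd.DataFrame,
    base: float = 2.0,
    ct_ceiling: float = 40.0,
) -> pd.DataFrame:
    """Charged fractions from a Ct table via the delta-delta-Ct inversion.

    ``records`` needs columns replicate, treatment (oxidized /
    non_oxidized), target, ct_target, ct_spike.  For each (replicate,
    target) pair: dCt = ct_target - ct_spike within each treatment, and
    fraction = base^(dCt_nonox - dCt_ox), clamped to [0, 1] with a
    ``clamped`` flag when the exponent is positive.  An oxidized-arm Ct at
    the ceiling means no detectable charged template: fraction 0 with a
    ``ceiling`` flag.
    """
    required = {"replicate", "treatment", "target", "ct_target", "ct_spike"}
    missing = required - set(records.columns)
    if missing:
        raise QuantError(f"Ct table missing columns: {sorted(missing)}")
    bad = set(records["treatment"]) - {OXIDIZED, NON_OXIDIZED}
    if bad:
        raise QuantError(f"unknown treatments {sorted(bad)}")

    rows = []
    for (rep, target), group in records.groupby(["replicate", "target"], sort=True):
        arms = {}
        for treatment, arm in group.groupby("treatment"):
            if len(arm) != 1:
                raise QuantError(
                    f"replicate {rep!r} target {target!r}: {len(arm)} "
                    f"{treatment} rows, expected exactly 1"
                )
            arms[treatment] = arm.iloc[0]
        if set(arms) != {OXIDIZED, NON_OXIDIZED}:
            raise QuantError(
                f"replicate {rep!r} target {target!r}: unpaired record "
                f"(have {sorted(arms)})"
            )
        flags: set[str] = set()
        d_ox = float(arms[OXIDIZED]["ct_target"]) - float(arms[OXIDIZED]["ct_spike"])
        d_non = float(arms[NON_OXIDIZED]["ct_target"]) - float(arms[NON_OXIDIZED]["ct_spike"])
        if float(arms[OXIDIZED]["ct_target"]) >= ct_ceiling:
            fraction = 0.0
            flags.add("ceiling")
        else:
            exponent = d_non - d_ox
            fraction = base ** exponent
            if fraction > 1.0:
                fraction = 1.0
                flags.add("clamped")
        rows.append(
            {
                "target": target,
                "replicate": rep,
                "fraction": fraction,
                "base": base,
                "delta_ct_oxidized": d_ox,
                "delta_ct_non_oxidized": d_non,
                "flags": ",".join(sorted(flags)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def holm_sidak(p_values: list[float]) -> list[float]:
    """Holm-Sidak step-down adjustment of raw p values (input order kept).

    The i-th smallest of m raw values (1-based) becomes
    1 - (1 - p)^(m - i + 1) with running maxima enforcing monotonicity.
    """
    from statsmodels.stats.multitest import multipletests

    if not p_values:
        return []
    _, adjusted, _, _ = multipletests(p_values, method="holm-sidak")
    return [float(p) for p in adjusted]


def compare_groups(values: pd.DataFrame, design: str) -> pd.DataFrame:
    """Replicate-level group comparison.

    ``values`` needs columns ``group`` and ``value`` (paired designs pair
    rows by order within group; an optional ``replicate`` column is used
    for ordering when present).  ``design`` is ``paired_two_group`` (paired
    two-sided t test) or ``multi_group`` (one-way ANOVA followed by
    Holm-Sidak-adjusted pairwise Welch comparisons).  Groups with all
    pairwise differences zero report t=0, p=1; a zero-variance nonzero
    difference is flagged degenerate with p reported as 0 (below machine
    resolution).
    """
    if not {"group", "value"} <= set(values.columns):
        raise QuantError("values table needs 'group' and 'value' columns")
    sort_cols = ["group"] + (["replicate"] if "replicate" in values.columns else [])
    values = values.sort_values(sort_cols, kind="stable")
    groups = {g: np.asarray(v["value"], dtype=float) for g, v in values.groupby("group")}
    for g, v in groups.items():
        if len(v) < 2:
            raise QuantError(f"group {g!r} has {len(v)} replicate(s); need >= 2")

    if design == "paired_two_group":
        if len(groups) != 2:
            raise QuantError(f"paired design needs exactly 2 groups, got {len(groups)}")
        (ga, a), (gb, b) = sorted(groups.items())
        if len(a) != len(b):
            raise QuantError("paired design requires equal replicate counts")
        diff = a - b
        degenerate = False
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        elif np.std(diff, ddof=1) == 0.0:
            t, p, degenerate = math.inf, 0.0, True
        else:
            t, p = stats.ttest_rel(a, b)
        return pd.DataFrame(
            [
                {
                    "comparison": f"{ga} vs {gb}",
                    "test": "paired_t",
                    "statistic": float(t),
                    "p_raw": float(p),
                    "p_adjusted": float(p),
                    "degenerate": degenerate,
                }
            ]
        )

    if design != "multi_group":
        raise QuantError(f"unknown design {design!r}")
    if len(groups) < 3:
        raise QuantError("multi_group design needs >= 3 groups")
    f_stat, f_p = stats.f_oneway(*groups.values())
    rows = [
        {
            "comparison": "all groups",
            "test": "one_way_anova",
            "statistic": float(f_stat),
            "p_raw": float(f_p),
            "p_adjusted": float(f_p),
            "degenerate": False,
        }
    ]
    pairs = list(itertools.combinations(sorted(groups), 2))
    raw = []
    t_stats = []
    for ga, gb in pairs:
        t, p = stats.ttest_ind(groups[ga], groups[gb])
        raw.append(float(p))
        t_stats.append(float(t))
    adjusted = holm_sidak(raw)
    for (ga, gb), t, p, padj in zip(pairs, t_stats, raw, adjusted):
        rows.append(
            {
                "comparison": f"{ga} vs {gb}",
                "test": "pairwise_t_holm_sidak",
                "statistic": t,
                "p_raw": p,
                "p_adjusted": padj,
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)
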
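"""Relative cloning frequencies, group statistics and ddCt qPCR quantification.

Relative cloning frequency — the fraction of sequenced amplicon clones from a
sample attributable to a locus — is the profiling proxy for that locus's
relative transcript level. Frequency tables keep loci, composite ambiguous
groups and (optionally) an explicit unassigned row; per-column percentages sum
to 100 up to rounding.

Two aggregation modes are first-class because they answer different questions:
``per_sample_mean`` (unweighted mean of per-sample frequencies, with range) and
``pooled`` (100 * sum of counts / sum of totals). They coincide only when all
samples contribute equal clone numbers.

Group comparisons follow the conventional decision path: Shapiro-Wilk per
group at alpha = 0.05, Welch t-test if both groups look normal, otherwise a
two-sample Wilcoxon rank-sum test (a paired signed-rank variant is available).
Relative qPCR quantification uses the ddCt model:
fold = 2^-((Ct_target - Ct_norm)_sample - (Ct_target - Ct_norm)_reference),
with the high-expression reference sample defined as fold 1.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

UNASSIGNED_LABEL = "unassigned"
TISSUES = ("motor_cortex", "occipital", "spinal_cord", "cerebellum", "hippocampus", "other")
CONDITIONS = ("ALS", "control")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the published tables).

    Decimal-based so that values like 1.005 (not exactly representable in
    binary) still round to 1.01.
    """
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class SampleMeta:
    """Metadata of one tissue sample ('patient number - region' naming)."""

    sample_id: str
    donor_id: str = ""
    tissue: str = "other"
    condition: str = "control"
    rin: Optional[float] = None
    age: Optional[float] = None
    sex: str = ""

    def __post_init__(self):
        if not self.sample_id:
            raise ValueError("sample_id required")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}")
        if self.rin is not None and not 1 <= self.rin <= 10:
            raise ValueError("RIN must lie in [1, 10]")


class FrequencyTable:
    """Sample-by-category clone counts with relative cloning frequencies.

    Rows are loci, composite ambiguous groups ("A|B") and optionally an
    explicit unassigned row; columns are samples. ``percentages`` are
    100 * count / column total at full precision; ``display()`` rounds
    half-up to 2 decimals as in the published tables.
    """

    def __init__(self, counts: pd.DataFrame, totals: Optional[pd.Series] = None):
        self.counts = counts.fillna(0).astype(int)
        self.totals = self.counts.sum(axis=0) if totals is None else totals.astype(int)
        bad = [c for c in self.counts.columns if self.counts[c].sum() != self.totals[c]]
        if bad:
            raise ValueError(f"column counts do not sum to totals for {bad}")

    @property
    def percentages(self) -> pd.DataFrame:
        return 100.0 * self.counts / self.totals

    def display(self, ndigits: int = 2) -> pd.DataFrame:
        return self.percentages.map(lambda x: round_half_up(x, ndigits))

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.index)

    def drop_unassigned(self) -> "FrequencyTable":
        """Restrict to assigned rows (denominator = assigned clones only)."""
        counts = self.counts.drop(index=[UNASSIGNED_LABEL], errors="ignore")
        return FrequencyTable(counts)

    def to_tsv(self, path) -> None:
        out = self.display().copy()
        out.loc["# clones"] = self.totals
        out.to_csv(path, sep="\t")


def frequency_table(
    assignments: Iterable,
    sample_of_read: dict[str, str],
    include_unassigned: bool = True,
) -> FrequencyTable:
    """Build a frequency table from read assignments.

    ``assignments`` yields objects with ``read_id`` and ``category``
    (ReadAssignment instances or equivalent); ``sample_of_read`` labels each
    read with its sample. Ambiguous reads contribute to their composite group
    row. Samples with zero reads are dropped with a warning. Unassigned reads
    are kept in denominators by default (configurable), the convention used by
    the published per-sample tables.
    """
    rows: dict[tuple[str, str], int] = {}
    for a in assignments:
        sample = sample_of_read[a.read_id]
        cat = a.category
        if not include_unassigned and cat == UNASSIGNED_LABEL:
            continue
        rows[(cat, sample)] = rows.get((cat, sample), 0) + 1
    if not rows:
        raise ValueError("no reads to tabulate")
    empty = sorted(set(sample_of_read.values()) - {s for _, s in rows})
    if empty:
        warnings.warn(f"samples with zero reads dropped: {empty}", stacklevel=2)
    frame = pd.Series(rows).unstack(fill_value=0)
    frame = frame.reindex(sorted(frame.columns), axis=1)
    return FrequencyTable(frame)


def aggregate(
    table: FrequencyTable,
    grouping: dict[str, str],
    mode: str = "per_sample_mean",
) -> pd.DataFrame:
    """Aggregate per-sample frequencies into group summaries.

    ``grouping`` maps sample_id -> group label. ``per_sample_mean`` averages
    each sample's frequency with equal weight and reports the min/max range;
    ``pooled`` divides summed counts by summed totals (each clone weighted
    equally). Output: one row per (category, group).
    """
    if mode not in ("per_sample_mean", "pooled"):
        raise ValueError("mode must be per_sample_mean or pooled")
    missing = [s for s in table.samples if s not in grouping]
    if missing:
        raise ValueError(f"samples missing from grouping: {missing}")
    groups: dict[str, list[str]] = {}
    for sample in table.samples:
        groups.setdefault(grouping[sample], []).append(sample)
    records = []
    pct = table.percentages
    for group, samples in groups.items():
        if not samples:
            raise ValueError(f"empty group {group!r}")
        for category in table.categories:
            if mode == "per_sample_mean":
                vals = pct.loc[category, samples]
                records.append(
                    {
                        "category": category,
                        "group": group,
                        "mode": mode,
                        "value": float(vals.mean()),
                        "min": float(vals.min()),
                        "max": float(vals.max()),
                        "n_samples": len(samples),
                    }
                )
            else:
                num = int(table.counts.loc[category, samples].sum())
                den = int(table.totals[samples].sum())
                records.append(
                    {
                        "category": category,
                        "group": group,
                        "mode": mode,
                        "value": 100.0 * num / den,
                        "count": num,
                        "total": den,
                        "n_samples": len(samples),
                    }
                )
    return pd.DataFrame.from_records(records)


def compare_groups(
    values_a: Iterable[float],
    values_b: Iterable[float],
    alpha: float = 0.05,
    paired: bool = False,
) -> dict:
    """Two-group comparison with a normality-gated test choice.

    Shapiro-Wilk per group at ``alpha``; if both groups are consistent with
    normality a Welch two-sample t-test is used, otherwise the two-sample
    Wilcoxon rank-sum test (or the signed-rank test for paired designs).
    Returns the test chosen, its statistic and p-value, and the Shapiro
    p-values.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("insufficient samples: need >= 3 values per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sw_a = stats.shapiro(a).pvalue if np.ptp(a) > 0 else 0.0
        sw_b = stats.shapiro(b).pvalue if np.ptp(b) > 0 else 0.0
    normal = sw_a > alpha and sw_b > alpha
    if normal:
        if np.array_equal(np.sort(a), np.sort(b)) and np.std(a) == 0:
            test, statistic, pvalue = "welch_t", 0.0, 1.0
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            test, statistic, pvalue = "welch_t", float(res.statistic), float(res.pvalue)
            if np.isnan(statistic):  # zero variance in both groups, equal means
                statistic, pvalue = 0.0, 1.0
    elif paired:
        if len(a) != len(b):
            raise ValueError("paired design requires equal group sizes")
        res = stats.wilcoxon(a, b)
        test, statistic, pvalue = "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue)
    else:
        res = stats.ranksums(a, b)
        test, statistic, pvalue = "wilcoxon_rank_sum", float(res.statistic), float(res.pvalue)
    return {
        "test": test,
        "statistic": statistic,
        "pvalue": pvalue,
        "shapiro_p": (float(sw_a), float(sw_b)),
        "normal": bool(normal),
        "n": (len(a), len(b)),
    }


def ddct_fold_change(
    ct_table: pd.DataFrame,
    reference_sample: str,
    target: str = "HML2_gag",
    normalizer: str = "GAPDH",
) -> pd.DataFrame:
    """Per-sample fold changes by the ddCt method.

    ``ct_table`` columns: sample_id, target, replicate, ct (one row per
    replicate measurement). dCt = mean Ct(target) - mean Ct(normalizer) per
    sample; ddCt = dCt(sample) - dCt(reference); fold = 2^-ddCt, so the
    reference sample has fold 1 by definition and any constant shift applied
    to all Ct values cancels. The fold's standard deviation is propagated from
    the replicate Ct spread (log-normal delta method).
    """
    required = {"sample_id", "target", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"ct_table needs columns {sorted(required)}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    def _dct(sample_frame: pd.DataFrame):
        t = sample_frame.loc[sample_frame["target"] == target, "ct"]
        n = sample_frame.loc[sample_frame["target"] == normalizer, "ct"]
        if t.empty or n.empty:
            return None
        var = 0.0
        if len(t) > 1:
            var += t.var(ddof=1) / len(t)
        if len(n) > 1:
            var += n.var(ddof=1) / len(n)
        return float(t.mean() - n.mean()), math.sqrt(var)

    per_sample = {}
    for sample_id, frame in ct_table.groupby("sample_id"):
        res = _dct(frame)
        if res is None:
            warnings.warn(f"sample {sample_id!r} lacks target or normalizer Cts; skipped", stacklevel=2)
            continue
        per_sample[sample_id] = res
    if reference_sample not in per_sample:
        raise ValueError(f"reference sample {reference_sample!r} missing target or normalizer rows")
    ref_dct = per_sample[reference_sample][0]
    rows = []
    for sample_id, (dct, sd) in per_sample.items():
        ddct = dct - ref_dct
        fold = 2.0 ** (-ddct)
        rows.append(
            {
                "sample_id": sample_id,
                "dct": dct,
                "ddct": ddct,
                "fold_change": fold,
                "fold_sd": fold * math.log(2) * sd,
                "is_reference": sample_id == reference_sample,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def qc_correlation(x: Iterable[float], y: Iterable[float]) -> float:
    """Coefficient of determination (R^2) of the least-squares line y ~ x.

    Used for QC scatter checks such as RNA integrity (RIN) against
    normalizer Ct values.
    """
    xv = np.asarray(list(x), dtype=float)
    yv = np.asarray(list(y), dtype=float)
    if len(xv) != len(yv) or len(xv) < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("values must be finite")
    if np.ptp(xv) == 0:
        raise ValueError("zero variance in x")
    if np.ptp(yv) == 0:
        return 0.0
    res = stats.linregress(xv, yv)
    return float(res.rvalue**2)


def benjamini_hochberg(pvalues: Iterable[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; no correction is applied by default)."""
    p = np.asarray(list(pvalues), dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * n / (rank + 1))
        adjusted[idx] = running
    return adjusted
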
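"""Per-population haplotype frequency profiles and profile comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

UNDETERMINED = "UNDETERMINED"
OTHER = "other"


@dataclass
class HaplotypeProfile:
    """Category -> count table for one population over a shared category
    list (which may include the collapse bucket ``other``)."""

    population_id: str
    category_list: list[str]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> np.ndarray:
        n = self.n_total
        if n == 0:
            return np.zeros(len(self.category_list))
        return np.array([self.counts.get(c, 0) / n for c in self.category_list])


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float


def calls_table(specimens, calls) -> pd.DataFrame:
    """Join specimen metadata with per-marker calls into one flat table
    (the pipeline's central intermediate; every downstream number is
    recomputable from it)."""
    by_id = {sp.specimen_id: sp for sp in specimens}
    rows = []
    for call in calls:
        sp = by_id[call.specimen_id]
        rows.append({
            "specimen_id": call.specimen_id,
            "site_code": sp.site_code,
            "province": sp.province,
            "host": sp.host.value,
            "region": sp.region.value,
            "coi_call": call.coi.value.value if call.coi else None,
            "base1164": call.coi.base1164 if call.coi else None,
            "base1287": call.coi.base1287 if call.coi else None,
            "tpi_call": call.tpi.value.value if call.tpi else None,
            "base183": call.tpi.base183 if call.tpi else None,
            "intron_status": call.intron.status.value if call.intron else None,
            "intron_hap_id": call.intron.haplotype_id if call.intron else None,
            "intron_hap_seq": call.intron.haplotype_seq if call.intron else None,
        })
    return pd.DataFrame(rows)


def build_profiles(
    table: pd.DataFrame,
    group_by: str | Sequence[str],
    category_col: str,
    panel: Sequence[str] | None = None,
) -> tuple[list[HaplotypeProfile], pd.DataFrame]:
    """Aggregate per-specimen calls into per-group frequency profiles.

    ``table`` holds one row per specimen with metadata columns and the call
    column ``category_col``.  Rows whose call is UNDETERMINED (or missing)
    are excluded from denominators and returned in the exclusion report.
    The shared category list is the union over groups in stable
    (first-seen) order; when an explicit ``panel`` is given, categories
    outside it collapse into ``other``.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    missing = [c for c in list(group_by) + [category_col] if c not in table.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    excluded = table[table[category_col].isna() | (table[category_col] == UNDETERMINED)]
    usable = table.drop(excluded.index)
    if usable.empty:
        raise ValueError("no groups: every record is excluded or the table is empty")

    def categorize(value: str) -> str:
        if panel is not None and value not in panel:
            return OTHER
        return value

    if panel is not None:
        shared = list(panel)
        if any(categorize(v) == OTHER for v in usable[category_col]):
            shared = shared + [OTHER] if OTHER not in shared else shared
    else:
        shared = list(dict.fromkeys(usable[category_col]))

    profiles = []
    for key, sub in usable.groupby(list(group_by), sort=True):
        pop_id = key if isinstance(key, str) else "/".join(str(k) for k in key)
        counts: dict[str, int] = {}
        for v in sub[category_col]:
            c = categorize(v)
            counts[c] = counts.get(c, 0) + 1
        profiles.append(HaplotypeProfile(pop_id, list(shared), counts))
    return profiles, excluded


def profiles_to_frame(profiles: Sequence[HaplotypeProfile]) -> pd.DataFrame:
    """Wide table: one row per population, one column per category, plus
    n_total; values are counts."""
    if not profiles:
        return pd.DataFrame()
    cats = profiles[0].category_list
    rows = []
    for p in profiles:
        row = {"population_id": p.population_id, "n_total": p.n_total}
        row.update({c: p.counts.get(c, 0) for c in cats})
        rows.append(row)
    return pd.DataFrame(rows)


def pearson_profile_matrix(
    profiles: Sequence[HaplotypeProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r (and two-sided p) between frequency profiles.

    r is computed on the frequency vectors over the shared category list;
    p comes from the t transform with df = categories - 2.  A
    zero-variance profile makes r undefined for its pairs (NaN, with a
    warning).  Returns (r_matrix, p_matrix) with unit diagonal.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    cats = profiles[0].category_list
    if len(cats) < 3:
        raise ValueError("need a shared category list of length >= 3")
    for p in profiles:
        if p.category_list != cats:
            raise ValueError("profiles must share one category list")
    names = [p.population_id for p in profiles]
    freqs = [p.frequencies() for p in profiles]
    k = len(profiles)
    r_mat = np.eye(k)
    p_mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.std(freqs[i]) == 0 or np.std(freqs[j]) == 0:
                logger.warning("zero-variance profile: r undefined for %s/%s",
                               names[i], names[j])
                r_mat[i, j] = r_mat[j, i] = np.nan
                p_mat[i, j] = p_mat[j, i] = np.nan
                continue
            res = stats.pearsonr(freqs[i], freqs[j])
            r_mat[i, j] = r_mat[j, i] = res.statistic
            p_mat[i, j] = p_mat[j, i] = res.pvalue
    return (pd.DataFrame(r_mat, index=names, columns=names),
            pd.DataFrame(p_mat, index=names, columns=names))


def bonferroni(p_matrix: pd.DataFrame) -> pd.DataFrame:
    """Optional multiple-testing correction for the Pearson p matrix
    (off-diagonal upper-triangle tests)."""
    k = len(p_matrix)
    m = k * (k - 1) // 2
    corrected = (p_matrix * m).clip(upper=1.0)
    np.fill_diagonal(corrected.values, 0.0)
    return corrected


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Ordinary one-way ANOVA on raw per-collection values."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    summaries = [(len(g), float(np.mean(g)), float(np.std(g, ddof=1)) if len(g) > 1 else 0.0)
                 for g in groups]
    if any(len(g) < 1 for g in groups):
        raise ValueError("empty group")
    return anova_oneway_from_summaries(summaries, _allow_n1=True)


def anova_oneway_from_summaries(
    summaries: Sequence[tuple[int, float, float]],
    *,
    _allow_n1: bool = False,
) -> AnovaResult:
    """One-way ANOVA reconstructed from (n, mean, sd) group summaries.

    SSB = sum n_i (mean_i - grand)^2 ; SSW = sum (n_i - 1) sd_i^2.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two groups")
    for n, _, _ in summaries:
        if n < 2 and not _allow_n1:
            raise ValueError("summary mode requires every group n >= 2")
    ns = np.array([s[0] for s in summaries], dtype=float)
    means = np.array([s[1] for s in summaries], dtype=float)
    sds = np.array([s[2] for s in summaries], dtype=float)
    N = ns.sum()
    grand = float(np.sum(ns * means) / N)
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds**2))
    df_b = len(summaries) - 1
    df_w = int(N) - len(summaries)
    if df_w < 1:
        raise ValueError("no within-group degrees of freedom")
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0.0:
        f = 0.0 if msb == 0.0 else float("inf")
    else:
        f = msb / msw
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(F=f, df_between=df_b, df_within=df_w, p_value=p)
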
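"""Differential A-to-I RNA editing between protein-isoform conditions.

Per-site edited/unedited read counts from nine libraries (three
conditions - empty vector EV, short isoform, long isoform - with three
replicates each) are filtered, summarised as merged editing levels, and
tested for differential editing: a per-replicate Fisher exact test
against the matched EV replicate, combination across replicates by
Fisher's method (chi2 = -2 sum ln p, 6 df), and BH correction across
sites. Sites are then classified as common or isoform-specific, with a
high-confidence tier requiring FDR <= 10% for one isoform and >= 90%
for the other.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import bh_fdr, fisher_exact_2x2, fisher_method_combine, wilcoxon_signed_rank

GROUPS = ("EV", "SHORT", "LONG")
N_REPLICATES = 3
MIN_EDITED = 5
MIN_TOTAL_COVERAGE = 50

DEFAULT_MANIFEST: dict[str, tuple[str, int]] = {
    f"{g}{k}": (g, k) for g in GROUPS for k in range(1, N_REPLICATES + 1)
}

CLASSIFICATIONS = (
    "NOT_DIFFERENTIAL", "COMMON",
    "LOW_CONF_SHORT", "HIGH_CONF_SHORT", "LOW_CONF_LONG", "HIGH_CONF_LONG",
)


def _validate_manifest(manifest: Mapping[str, tuple[str, int]]) -> None:
    pairs = sorted(manifest.values())
    expected = sorted((g, k) for g in GROUPS for k in range(1, N_REPLICATES + 1))
    if pairs != expected:
        raise ValueError(
            "library manifest must cover exactly 3 replicates of each of "
            f"{GROUPS}; got {pairs}"
        )


class EditingCounts:
    """Per-site edited/unedited counts across the nine libraries.

    ``table`` has columns site_id, chrom, pos, strand, then ``e_<LIB>`` and
    ``u_<LIB>`` for each library in the manifest.
    """

    def __init__(self, table: pd.DataFrame, manifest: Mapping[str, tuple[str, int]] | None = None):
        self.manifest = dict(manifest or DEFAULT_MANIFEST)
        _validate_manifest(self.manifest)
        for lib in self.manifest:
            for col in (f"e_{lib}", f"u_{lib}"):
                if col not in table.columns:
                    raise ValueError(f"missing count column {col}")
                if (table[col] < 0).any():
                    raise ValueError(f"negative counts in {col}")
        if "site_id" not in table.columns:
            table = table.assign(
                site_id=table["chrom"].astype(str) + ":" + table["pos"].astype(str)
                + ":" + table["strand"].astype(str)
            )
        self.table = table.reset_index(drop=True)

    def libraries(self, group: str) -> list[str]:
        libs = [lib for lib, (g, _) in self.manifest.items() if g == group]
        return sorted(libs, key=lambda lib: self.manifest[lib][1])

    def subset(self, mask: np.ndarray | pd.Series) -> "EditingCounts":
        return EditingCounts(self.table[mask].reset_index(drop=True), self.manifest)

    def __len__(self) -> int:
        return len(self.table)


def filter_sites(counts: EditingCounts, min_edited: int = MIN_EDITED) -> EditingCounts:
    """Remove unreliable or uninformative sites.

    A site is kept iff (i) at least one of the nine libraries has at least
    ``min_edited`` edited reads, and (ii) every condition group has read
    coverage (edited + unedited > 0) in at least one replicate.
    """
    t = counts.table
    e_cols = [f"e_{lib}" for lib in counts.manifest]
    keep = t[e_cols].max(axis=1) >= min_edited
    for group in GROUPS:
        keep &= cov_any(t, counts.libraries(group))
    return counts.subset(keep)


def cov_any(t: pd.DataFrame, libs: Sequence[str]) -> pd.Series:
    """True where any of the listed libraries has nonzero coverage."""
    any_cov = pd.Series(False, index=t.index)
    for lib in libs:
        any_cov |= (t[f"e_{lib}"] + t[f"u_{lib}"]) > 0
    return any_cov


def merged_editing_levels(counts: EditingCounts, group: str) -> pd.DataFrame:
    """Replicate-merged editing level per site for one condition group.

    Reads of the three replicates are pooled; the level is the edited
    fraction of the pooled counts (NaN when the pooled coverage is zero).
    Returns columns site_id, level, total.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    t = counts.table
    libs = counts.libraries(group)
    e = sum(t[f"e_{lib}"] for lib in libs)
    total = e + sum(t[f"u_{lib}"] for lib in libs)
    level = np.where(total > 0, e / total.replace(0, np.nan), np.nan)
    return pd.DataFrame({"site_id": t["site_id"], "level": level, "total": total})


@dataclass
class GlobalComparison:
    n_sites: int
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    p: float


def global_comparison(
    levels_a: pd.DataFrame, levels_b: pd.DataFrame, min_total: int = MIN_TOTAL_COVERAGE
) -> GlobalComparison:
    """Compare overall editing levels between two groups.

    Only sites with pooled coverage >= ``min_total`` and a defined level
    in both groups are used; the levels of the shared sites are compared
    with a paired two-tailed Wilcoxon signed-rank test.
    """
    m = levels_a.merge(levels_b, on="site_id", suffixes=("_a", "_b"))
    m = m[(m["total_a"] >= min_total) & (m["total_b"] >= min_total)]
    m = m.dropna(subset=["level_a", "level_b"])
    if len(m) < 2:
        raise ValueError("fewer than 2 shared gated sites")
    a, b = m["level_a"].to_numpy(), m["level_b"].to_numpy()
    return GlobalComparison(
        n_sites=len(m),
        mean_a=float(a.mean()), se_a=float(a.std(ddof=1) / np.sqrt(len(a))),
        mean_b=float(b.mean()), se_b=float(b.std(ddof=1) / np.sqrt(len(b))),
        p=wilcoxon_signed_rank(a, b),
    )


def differential_editing(
    counts: EditingCounts,
    isoform_group: str,
    ev_group: str = "EV",
    pairing: str = "indexed",
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Replicate-combined differential-editing test for one isoform.

    Per replicate k, a two-sided Fisher exact test compares the site's
    edited/unedited counts in the isoform's replicate k with EV (matched
    replicate k under ``pairing='indexed'``, or the pooled EV counts under
    ``pairing='pooled-EV'``). The three p-values are combined by Fisher's
    method (6 df) and BH-corrected across sites. A replicate pair without
    any coverage contributes p = 1 and is flagged.
    """
    if pairing not in ("indexed", "pooled-EV"):
        raise ValueError("pairing must be 'indexed' or 'pooled-EV'")
    t = counts.table
    iso_libs = counts.libraries(isoform_group)
    ev_libs = counts.libraries(ev_group)
    ev_e_pool = sum(t[f"e_{lib}"] for lib in ev_libs)
    ev_u_pool = sum(t[f"u_{lib}"] for lib in ev_libs)

    n = len(t)
    rep_p = np.ones((n, N_REPLICATES))
    zero_cov = np.zeros(n, dtype=bool)
    underflow = np.zeros(n, dtype=bool)
    for i in range(n):
        for k in range(N_REPLICATES):
            e1 = int(t.at[i, f"e_{iso_libs[k]}"])
            u1 = int(t.at[i, f"u_{iso_libs[k]}"])
            if pairing == "indexed":
                e0 = int(t.at[i, f"e_{ev_libs[k]}"])
                u0 = int(t.at[i, f"u_{ev_libs[k]}"])
            else:
                e0, u0 = int(ev_e_pool.iat[i]), int(ev_u_pool.iat[i])
            table = np.array([[e1, u1], [e0, u0]])
            if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
                rep_p[i, k] = 1.0
                if e1 + u1 == 0 or e0 + u0 == 0:
                    zero_cov[i] = True
                continue
            _, rep_p[i, k] = fisher_exact_2x2(table)

    tiny = sys.float_info.min
    underflow = (rep_p <= 0).any(axis=1)
    rep_p = np.clip(rep_p, tiny, 1.0)
    chi2 = np.empty(n)
    p_comb = np.empty(n)
    for i in range(n):
        chi2[i], _, p_comb[i] = fisher_method_combine(rep_p[i])
    q = bh_fdr(p_comb) if n else np.empty(0)
    out = pd.DataFrame({
        "site_id": t["site_id"],
        "p_rep1": rep_p[:, 0], "p_rep2": rep_p[:, 1], "p_rep3": rep_p[:, 2],
        "chi2": chi2, "p_combined": p_comb, "q": q,
        "zero_coverage_replicate": zero_cov,
        "p_underflow": underflow,
    })
    out["differential"] = out["q"] <= fdr_threshold
    return out


def classify_specificity(
    calls_short: pd.DataFrame,
    calls_long: pd.DataFrame,
    q_low: float = 0.10,
    q_high: float = 0.90,
) -> pd.DataFrame:
    """Combine per-isoform q-values into a common/isoform-specific call.

    COMMON: both q <= q_low. HIGH_CONF_X: q_X <= q_low while the other
    isoform's q >= q_high. LOW_CONF_X: q_X <= q_low with the other q in
    (q_low, q_high). Otherwise NOT_DIFFERENTIAL. Sites missing a q-value
    on either side are skipped and flagged in the attrs of the result.
    """
    m = calls_short[["site_id", "q"]].merge(
        calls_long[["site_id", "q"]], on="site_id", how="outer",
        suffixes=("_short", "_long"),
    )
    skipped = m["q_short"].isna() | m["q_long"].isna()
    m = m[~skipped].reset_index(drop=True)

    def classify(qs: float, ql: float) -> str:
        if qs <= q_low and ql <= q_low:
            return "COMMON"
        for q_x, q_o, label in ((qs, ql, "SHORT"), (ql, qs, "LONG")):
            if q_x <= q_low:
                if q_o >= q_high:
                    return f"HIGH_CONF_{label}"
                return f"LOW_CONF_{label}"
        return "NOT_DIFFERENTIAL"

    m["classification"] = [
        classify(qs, ql) for qs, ql in zip(m["q_short"], m["q_long"])
    ]
    m.attrs["skipped_missing_q"] = int(skipped.sum())
    return m
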
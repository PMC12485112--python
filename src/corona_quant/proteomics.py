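"""Label-free proteomics: Hi3 absolute quantification and corona enrichment.

The quantification layer turns peptide-level intensities into absolute
protein abundances (fmol) by scaling the mean of each protein's three most
intense peptides to a spiked internal standard of known amount (Hi3 / top-3,
50 fmol E. coli ClpB per 5 uL by default).  The enrichment layer compares
protein abundances between the LNP-corona sample and the plasma-alone
control: log2 fold change, Welch t on log2 abundances, Benjamini-Hochberg q
values, and an enriched / depleted / not-significant call at q < 0.05.
Cross-batch consistency and a local EASE-score over-representation test on
user-supplied annotation maps complete the layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "hi3_quantify",
    "CvSummary",
    "peptide_cv_summary",
    "EnrichmentResult",
    "enrichment_analysis",
    "RankComparison",
    "rank_comparison",
    "consistent_enrichment",
    "AnnotationMap",
    "ease_overrepresentation",
]

RUN_KEYS = ["condition", "replicate_id", "batch_id"]


def _filter_missing_peptides(peptides: pd.DataFrame) -> pd.DataFrame:
    """Drop peptides missing in more than one replicate of a condition/batch.

    A peptide with fewer than (n_replicates - 1) finite intensities within a
    (condition, batch) group is excluded from quantification of those runs.
    """
    df = peptides.copy()
    df["finite"] = np.isfinite(df["intensity"])
    grp = df.groupby(["peptide_id", "condition", "batch_id"], sort=False)
    n_reps = df.groupby(["condition", "batch_id"], sort=False)["replicate_id"].transform(
        "nunique"
    )
    n_finite = grp["finite"].transform("sum")
    keep = df["finite"] & (n_finite >= n_reps - 1)
    dropped = df.loc[~keep & df["finite"], "peptide_id"].nunique()
    if dropped:
        logger.info("excluded %d peptides with excess missingness", dropped)
    return df[keep].drop(columns="finite")


def _top_n_mean(intensities: pd.Series, n: int = 3) -> tuple[float, int]:
    """Mean of the top-n intensities; ties broken by peptide_id order."""
    ordered = intensities.sort_index().sort_values(ascending=False, kind="stable")
    top = ordered.iloc[:n]
    return float(top.mean()), int(len(top))


def hi3_quantify(
    peptides: pd.DataFrame,
    standard_accession: str = "P63284",
    spike_fmol: float = 50.0,
) -> pd.DataFrame:
    """Hi3 absolute quantification against the spiked internal standard.

    Per run (condition x replicate x batch), a protein's abundance is

        spike_fmol * mean(top-3 peptide intensities of the protein)
                   / mean(top-3 peptide intensities of the standard).

    Proteins with fewer than 3 quantifiable peptides use all available
    peptides and are flagged.  Returns a tidy table with columns
    protein_accession, condition, replicate_id, batch_id, abundance_fmol,
    n_peptides_used, flagged.
    """
    if spike_fmol <= 0:
        raise ValueError("spike_fmol must be > 0")
    required = {"peptide_id", "protein_accession", "intensity", *RUN_KEYS}
    missing = required - set(peptides.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    usable = _filter_missing_peptides(peptides)

    rows = []
    for run, run_df in usable.groupby(RUN_KEYS, sort=False):
        std = run_df[run_df["protein_accession"] == standard_accession]
        if std.empty:
            raise ValueError(
                f"internal standard {standard_accession!r} absent from run "
                f"{dict(zip(RUN_KEYS, run))}"
            )
        std_mean, _ = _top_n_mean(std.set_index("peptide_id")["intensity"])
        for acc, prot_df in run_df.groupby("protein_accession", sort=False):
            mean_int, n_used = _top_n_mean(prot_df.set_index("peptide_id")["intensity"])
            rows.append(
                (
                    acc,
                    *run,
                    # ratio first: the standard's self-ratio is exactly 1.0,
                    # so its abundance is exactly the spike amount
                    spike_fmol * (mean_int / std_mean),
                    n_used,
                    n_used < 3,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_accession",
            *RUN_KEYS,
            "abundance_fmol",
            "n_peptides_used",
            "flagged",
        ],
    )


@dataclass
class CvSummary:
    """Per-peptide CV% across technical replicates and per-condition medians."""

    per_peptide: pd.DataFrame  # peptide_id, condition, batch_id, cv_pct
    median_cv_pct: dict[str, float]


def peptide_cv_summary(peptides: pd.DataFrame) -> CvSummary:
    """CV% = 100 * sample sd / mean of a peptide's replicate intensities.

    Computed per (peptide, condition, batch); peptides with fewer than two
    finite replicate intensities are excluded, zero-mean peptides are
    excluded with a warning.  The summary value is the median over peptides
    within each condition.
    """
    df = peptides[np.isfinite(peptides["intensity"])]
    grp = df.groupby(["peptide_id", "condition", "batch_id"])["intensity"]
    agg = grp.agg(["mean", "std", "count"]).reset_index()
    agg = agg[agg["count"] >= 2]
    zero_mean = agg["mean"] == 0
    if zero_mean.any():
        warnings.warn(
            f"excluded {int(zero_mean.sum())} peptides with zero mean intensity",
            stacklevel=2,
        )
        agg = agg[~zero_mean]
    if agg.empty:
        raise ValueError("no peptide has >= 2 finite replicate intensities")
    agg["cv_pct"] = 100.0 * agg["std"] / agg["mean"]
    per_peptide = agg[["peptide_id", "condition", "batch_id", "cv_pct"]]
    medians = per_peptide.groupby("condition")["cv_pct"].median().to_dict()
    return CvSummary(per_peptide=per_peptide.reset_index(drop=True), median_cv_pct=medians)


@dataclass
class EnrichmentResult:
    """Per-protein enrichment records plus proteins seen in only one condition."""

    records: pd.DataFrame  # protein_accession, log2_fc, mean_fmol_lnp, p_value, q_value, cls
    lnp_only: list[str] = field(default_factory=list)
    plasma_only: list[str] = field(default_factory=list)
    q_threshold: float = 0.05

    @property
    def enriched(self) -> set[str]:
        rec = self.records
        return set(rec.loc[rec["cls"] == "enriched", "protein_accession"])

    @property
    def depleted(self) -> set[str]:
        rec = self.records
        return set(rec.loc[rec["cls"] == "depleted", "protein_accession"])


def _impute_run_zeros(abundances: pd.DataFrame) -> pd.DataFrame:
    """Replace zero abundances by half the smallest nonzero value in the run."""
    df = abundances.copy()
    zeros = df["abundance_fmol"] == 0
    if not zeros.any():
        return df
    for run, run_df in df.groupby(RUN_KEYS, sort=False):
        z = zeros.loc[run_df.index]
        if not z.any():
            continue
        nonzero = run_df.loc[run_df["abundance_fmol"] > 0, "abundance_fmol"]
        if nonzero.empty:
            raise ValueError(f"run {run} has no nonzero abundances")
        floor = 0.5 * float(nonzero.min())
        df.loc[run_df.index[z], "abundance_fmol"] = floor
        logger.info("run %s: imputed %d zero abundances at %.3g", run, int(z.sum()), floor)
    return df


def enrichment_analysis(
    abundances: pd.DataFrame,
    q_threshold: float = 0.05,
    lnp_condition: str = "LNP",
    control_condition: str = "PLASMA",
    exclude_accessions: Iterable[str] = (),
) -> EnrichmentResult:
    """Corona enrichment relative to the biofluid-alone control.

    Only proteins quantified in both conditions (with >= 2 replicates each)
    are tested:  log2FC = mean(log2 abundance, LNP) - mean(log2 abundance,
    control), p from a Welch two-sample t test on log2 abundances, q from
    Benjamini-Hochberg across all tested proteins.  Proteins detected in a
    single condition are listed separately rather than given infinite fold
    changes.  ``exclude_accessions`` removes e.g. the spiked standard.
    """
    df = abundances[~abundances["protein_accession"].isin(set(exclude_accessions))]
    df = _impute_run_zeros(df)

    rows = []
    lnp_only: list[str] = []
    plasma_only: list[str] = []
    for acc, prot in df.groupby("protein_accession", sort=False):
        x = prot.loc[prot["condition"] == lnp_condition, "abundance_fmol"].to_numpy()
        y = prot.loc[prot["condition"] == control_condition, "abundance_fmol"].to_numpy()
        if len(y) < 2 and len(x) >= 2:
            lnp_only.append(acc)
            continue
        if len(x) < 2 and len(y) >= 2:
            plasma_only.append(acc)
            continue
        if len(x) < 2 or len(y) < 2:
            continue
        lx, ly = np.log2(x), np.log2(y)
        log2_fc = float(lx.mean() - ly.mean())
        if np.ptp(lx) == 0 and np.ptp(ly) == 0:
            p = 1.0 if lx.mean() == ly.mean() else 0.0
            p = max(p, np.finfo(float).tiny)
        else:
            p = float(stats.ttest_ind(lx, ly, equal_var=False).pvalue)
        rows.append((acc, log2_fc, float(x.mean()), p))

    records = pd.DataFrame(
        rows, columns=["protein_accession", "log2_fc", "mean_fmol_lnp", "p_value"]
    )
    if not records.empty:
        records["q_value"] = multipletests(records["p_value"], method="fdr_bh")[1]
        sig = records["q_value"] < q_threshold
        records["cls"] = "not_significant"
        records.loc[sig & (records["log2_fc"] > 0), "cls"] = "enriched"
        records.loc[sig & (records["log2_fc"] < 0), "cls"] = "depleted"
    else:
        records["q_value"] = []
        records["cls"] = []
    return EnrichmentResult(
        records=records,
        lnp_only=lnp_only,
        plasma_only=plasma_only,
        q_threshold=q_threshold,
    )


@dataclass
class RankComparison:
    n: int
    pearson_r: float
    spearman_rho: float
    subset_n: int | None = None
    subset_pearson_r: float | None = None
    subset_spearman_rho: float | None = None


def _safe_corrs(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), float("nan")
    return (
        float(stats.pearsonr(a, b).statistic),
        float(stats.spearmanr(a, b).statistic),
    )


def rank_comparison(
    records: pd.DataFrame,
    lnp_relative_abundance_pct: Mapping[str, float],
    subset: Iterable[str] | None = None,
) -> RankComparison:
    """Correlate corona log2 fold change with LNP-only relative abundance (%).

    This contrasts the control-normalized analysis with the older practice of
    ranking corona proteins by their relative abundance in the LNP sample
    alone (which is biased toward proteins abundant in plasma).  Degenerate
    constant vectors yield NaN correlations.
    """
    shared = records[records["protein_accession"].isin(lnp_relative_abundance_pct)]
    if len(shared) < 3:
        raise ValueError("need >= 3 proteins shared between the two rankings")
    fc = shared["log2_fc"].to_numpy()
    rel = np.array([lnp_relative_abundance_pct[a] for a in shared["protein_accession"]])
    pear, spear = _safe_corrs(fc, rel)
    out = RankComparison(n=len(shared), pearson_r=pear, spearman_rho=spear)
    if subset is not None:
        sub = shared[shared["protein_accession"].isin(set(subset))]
        if len(sub) >= 3:
            fc_s = sub["log2_fc"].to_numpy()
            rel_s = np.array(
                [lnp_relative_abundance_pct[a] for a in sub["protein_accession"]]
            )
            out.subset_pearson_r, out.subset_spearman_rho = _safe_corrs(fc_s, rel_s)
            out.subset_n = len(sub)
    return out


def consistent_enrichment(
    batches: Sequence[EnrichmentResult],
) -> tuple[set[str], pd.DataFrame]:
    """Proteins classified enriched in every batch, plus per-protein counts.

    Returns the consistent set and a table (protein_accession,
    n_batches_enriched) over proteins enriched in at least one batch.
    """
    if len(batches) == 0:
        raise ValueError("need at least one batch")
    enriched_sets = [b.enriched for b in batches]
    consistent = set.intersection(*enriched_sets)
    counts: dict[str, int] = {}
    for s in enriched_sets:
        for acc in s:
            counts[acc] = counts.get(acc, 0) + 1
    table = (
        pd.DataFrame(
            sorted(counts.items()), columns=["protein_accession", "n_batches_enriched"]
        )
        if counts
        else pd.DataFrame(columns=["protein_accession", "n_batches_enriched"])
    )
    return consistent, table


@dataclass
class AnnotationMap:
    """Annotation terms (e.g. GO) mapped to protein accessions."""

    terms: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        self.background = set(self.background)
        self.terms = {t: set(m) for t, m in self.terms.items()}


def ease_overrepresentation(
    query: set[str],
    annotations: AnnotationMap,
    min_count: int = 5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Local over-representation test with the EASE-score correction.

    The EASE score is a conservative one-sided Fisher exact p value in which
    one member is removed from the observed overlap (floored at zero) before
    building the 2x2 table.  A term passes when overlap count >= ``min_count``
    and EASE p <= ``p_threshold`` (defaults 5 and 0.05).  Terms extending
    outside the background space are skipped with a warning.
    """
    query = set(query)
    if not query <= annotations.background:
        raise ValueError("query must be a subset of the annotation background")
    n_bg = len(annotations.background)
    n_q = len(query)
    rows = []
    for term_id, members in annotations.terms.items():
        if not members <= annotations.background:
            warnings.warn(f"term {term_id!r} not within background; skipped", stacklevel=2)
            continue
        count = len(query & members)
        a = max(count - 1, 0)
        table = [
            [a, n_q - a],
            [len(members) - a, n_bg - n_q - len(members) + a],
        ]
        ease_p = float(stats.fisher_exact(table, alternative="greater").pvalue)
        rows.append((term_id, count, ease_p, count >= min_count and ease_p <= p_threshold))
    return pd.DataFrame(rows, columns=["term_id", "count", "ease_p", "passed"])
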
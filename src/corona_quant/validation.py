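"""Calibration and recovery studies run on the synthetic generators.

These are the package's self-checks, exercised by the test suite and the
reproduction script: false-discovery-rate control of the enrichment analysis
under a null proteome, log2 fold-change recovery at a known effect size,
imaging fold-change and outer-fraction recovery against placement truth, and
type-I-error calibration of the nested and repeated-measures ANOVA + Dunnett
procedures.  Every study runs the *real* analysis path end to end on freshly
generated data; nothing is approximated or short-circuited.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._random import substream
from .imaging import measure_fov
from .proteomics import enrichment_analysis, hi3_quantify
from .stats import nested_anova_dunnett, rm_anova_gg_dunnett
from .synthetic import FovSimConfig, ProteomeSimConfig, gen_fov, gen_peptide_table

__all__ = [
    "null_proteome_fdr",
    "log2fc_recovery",
    "imaging_fold_change_ratio",
    "outer_fraction_recovery",
    "nested_anova_type_i_error",
    "rm_anova_type_i_error",
]


def _child_seeds(seed: int, label: str, n: int) -> np.ndarray:
    return substream(seed, "validation", label).integers(2**31, size=n)


def null_proteome_fdr(
    n_seeds: int = 200,
    seed: int = 0,
    n_proteins: int = 30,
    peptides_per_protein: int = 4,
    q_threshold: float = 0.05,
) -> float:
    """Mean fraction of proteins called enriched or depleted when nothing is.

    All true log2 fold changes are zero; under Benjamini-Hochberg control the
    average fraction of (false) discoveries must not exceed the q threshold.
    """
    fractions = []
    fc = {f"NULL{i:03d}": 0.0 for i in range(n_proteins)}
    for s in _child_seeds(seed, "null-fdr", n_seeds):
        cfg = ProteomeSimConfig(
            n_proteins=n_proteins,
            peptides_per_protein=peptides_per_protein,
            true_log2fc=fc,
            seed=int(s),
        )
        table, truth = gen_peptide_table(cfg)
        ab = hi3_quantify(table, truth.standard_accession, truth.spike_fmol)
        res = enrichment_analysis(
            ab, q_threshold=q_threshold, exclude_accessions=[truth.standard_accession]
        )
        n_called = len(res.enriched) + len(res.depleted)
        fractions.append(n_called / len(res.records))
    return float(np.mean(fractions))


def log2fc_recovery(
    n_seeds: int = 200,
    seed: int = 0,
    true_fc: float = 2.0,
    replicate_cv: float = 0.12,
    n_replicates: int = 3,
    n_proteins: int = 10,
) -> np.ndarray:
    """Estimated log2FC of a single truly-changed protein across seeds.

    One protein carries the true effect; the rest are null.  Returns the
    per-seed estimates from the full Hi3 -> enrichment path.
    """
    fc = {f"P{i:03d}": 0.0 for i in range(n_proteins)}
    target = "P000"
    fc[target] = true_fc
    estimates = []
    for s in _child_seeds(seed, "fc-recovery", n_seeds):
        cfg = ProteomeSimConfig(
            n_proteins=n_proteins,
            peptides_per_protein=4,
            true_log2fc=fc,
            replicate_cv=replicate_cv,
            plasma_replicate_cv=replicate_cv,
            n_replicates=n_replicates,
            seed=int(s),
        )
        table, truth = gen_peptide_table(cfg)
        ab = hi3_quantify(table, truth.standard_accession, truth.spike_fmol)
        res = enrichment_analysis(ab, exclude_accessions=[truth.standard_accession])
        rec = res.records.set_index("protein_accession")
        estimates.append(float(rec.loc[target, "log2_fc"]))
    return np.asarray(estimates)


def imaging_fold_change_ratio(
    fold: float = 5.0,
    base_rate: float = 5.0,
    n_fovs: int = 12,
    seed: int = 0,
) -> float:
    """Measured cy5-per-cell ratio between two conditions differing only in
    the inner-punctum rate by ``fold``."""
    def condition_mean(rate: float, label: str) -> float:
        vals = []
        for i, s in enumerate(_child_seeds(seed, f"fold-{label}", n_fovs)):
            cfg = FovSimConfig(
                puncta_per_cell_inner=rate,
                puncta_per_cell_outer=0.0,
                puncta_per_cell_lyso=0.0,
                lysosomes_per_cell=0,
                seed=int(s),
            )
            fov, _ = gen_fov(cfg, fov_index=i)
            vals.append(measure_fov(fov).cy5_per_cell)
        return float(np.mean(vals))

    return condition_mean(base_rate * fold, "hi") / condition_mean(base_rate, "lo")


def outer_fraction_recovery(
    inner_rate: float = 9.0,
    outer_rate: float = 1.0,
    n_fovs: int = 12,
    seed: int = 0,
) -> tuple[float, float]:
    """(measured, placement-truth) mean outer Cy5 fraction over FOVs."""
    est, tru = [], []
    for i, s in enumerate(_child_seeds(seed, "outer-frac", n_fovs)):
        cfg = FovSimConfig(
            puncta_per_cell_inner=inner_rate,
            puncta_per_cell_outer=outer_rate,
            puncta_per_cell_lyso=0.0,
            lysosomes_per_cell=0,
            seed=int(s),
        )
        fov, truth = gen_fov(cfg, fov_index=i)
        est.append(measure_fov(fov).outer_fraction)
        tru.append(truth.true_outer_fraction)
    return float(np.mean(est)), float(np.mean(tru))


def _replicate_frame(values: np.ndarray) -> pd.DataFrame:
    n_cond, n_bio, n_sub = values.shape
    rows = []
    for c in range(n_cond):
        cond = "control" if c == 0 else f"t{c}"
        for b in range(n_bio):
            for t in range(n_sub):
                rows.append((cond, f"bio{b}", f"tech{t}", values[c, b, t]))
    return pd.DataFrame(
        rows,
        columns=["condition", "biological_replicate", "technical_replicate", "value"],
    )


def nested_anova_type_i_error(
    n_reps: int = 2000,
    seed: int = 0,
    n_conditions: int = 5,
    n_bio: int = 3,
    n_sub: int = 4,
    alpha: float = 0.05,
) -> float:
    """Family-wise rejection rate of nested ANOVA + Dunnett under the null.

    Data carry a biological-replicate random effect plus technical noise but
    no condition effect; the fraction of simulations with any significant
    Dunnett comparison estimates the family-wise type-I error.
    """
    rng = substream(seed, "validation", "nested-null")
    rejections = 0
    for _ in range(n_reps):
        vals = rng.normal(0, 1, (n_conditions, n_bio, 1)) + rng.normal(
            0, 1, (n_conditions, n_bio, n_sub)
        )
        res = nested_anova_dunnett(_replicate_frame(vals), control="control", alpha=alpha)
        if any(c.significant for c in res.comparisons):
            rejections += 1
    return rejections / n_reps


def rm_anova_type_i_error(
    n_reps: int = 2000,
    seed: int = 0,
    n_conditions: int = 4,
    n_bio: int = 4,
    alpha: float = 0.05,
) -> float:
    """Family-wise rejection rate of RM ANOVA + GG + Dunnett under the null
    (compound-symmetric blocks: subject effect plus independent noise)."""
    rng = substream(seed, "validation", "rm-null")
    rejections = 0
    for _ in range(n_reps):
        vals = (
            rng.normal(0, 1, (n_conditions, n_bio, 1))
            + rng.normal(0, 1, (1, n_bio, 1))
        )
        res = rm_anova_gg_dunnett(
            _replicate_frame(vals), control="control", alpha=alpha
        )
        if any(c.significant for c in res.comparisons):
            rejections += 1
    return rejections / n_reps
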
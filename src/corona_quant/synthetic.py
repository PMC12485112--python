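"""Synthetic data generators with recorded ground truth.

Every input the analysis pipeline consumes can be generated here:

* density-gradient fraction profiles (fluorescence / absorbance / refractive
  index of a 24 x 0.5 mL iodixanol gradient, with a sharp early LNP peak and a
  broad minor late peak from fluorophore dissociation),
* peptide-level label-free intensity tables with a spiked internal-standard
  protein for Hi3 absolute quantification,
* multi-channel microscopy fields of view (nuclei / membrane-or-lysosome /
  Cy5-mRNA puncta placed in inner, outer-rim, and lysosomal compartments),
* per-event flow-cytometry fluorescence vectors.

Each generator returns ``(data, truth)`` where the truth object records the
exact quantities the downstream estimators are supposed to recover, and is
JSON-serializable via ``to_dict``.  All randomness flows from the single
``seed`` field of each config through :func:`corona_quant._random.substream`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from ._random import substream

__all__ = [
    "FractionSimConfig",
    "FractionTruth",
    "gen_fraction_profile",
    "ProteomeSimConfig",
    "ProteomeTruth",
    "study_effect_structure",
    "observed_to_population_cv",
    "gen_peptide_table",
    "FovSimConfig",
    "FovTruth",
    "ImageFOV",
    "gen_fov",
    "FlowTruth",
    "gen_flow_sample",
]

# arbitrary detector counts per fmol of peptide; cancels in all ratios
INTENSITY_PER_FMOL = 100.0


# ---------------------------------------------------------------------------
# fraction profiles
# ---------------------------------------------------------------------------

@dataclass
class FractionSimConfig:
    """Density-gradient fluorescence profile simulation.

    The defaults reproduce the study geometry: 24 fractions of 0.5 mL, a
    single sharp LNP peak in the early fractions carrying ~68% of the total
    (baseline-free) fluorescence mass, and a broad minor late peak carrying
    the remainder (free-fluorophore dissociation).  Plasma autofluorescence is
    negligible, so the baseline defaults near zero.
    """

    n_fractions: int = 24
    peak_center: float = 4.0
    peak_sd: float = 0.75
    peak_mass: float = 68.0
    late_peak_center: float = 14.0
    late_peak_sd: float = 4.0
    late_peak_mass: float = 32.0
    baseline: float = 0.1
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_fractions < 2:
            raise ValueError("n_fractions must be >= 2")
        if self.peak_sd <= 0 or self.late_peak_sd <= 0:
            raise ValueError("peak standard deviations must be > 0")
        if self.peak_mass < 0 or self.late_peak_mass < 0:
            raise ValueError("peak masses must be >= 0")
        if self.peak_mass + self.late_peak_mass <= 0:
            raise ValueError("at least one peak must carry positive mass")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class FractionTruth:
    """Noiseless per-fraction peak components of a simulated gradient."""

    fraction_index: np.ndarray
    peak_component: np.ndarray
    late_component: np.ndarray

    def pct_in_window(self, start: int, end: int) -> float:
        """Exact percent of total baseline-free peak mass in [start, end]."""
        sel = (self.fraction_index >= start) & (self.fraction_index <= end)
        total = float(self.peak_component.sum() + self.late_component.sum())
        inside = float(self.peak_component[sel].sum() + self.late_component[sel].sum())
        return 100.0 * inside / total

    def to_dict(self) -> dict:
        return {
            "fraction_index": self.fraction_index.tolist(),
            "peak_component": self.peak_component.tolist(),
            "late_component": self.late_component.tolist(),
            "pct_in_window_2_6": self.pct_in_window(2, 6),
        }


def _discrete_gaussian_mass(idx: np.ndarray, center: float, sd: float, mass: float) -> np.ndarray:
    w = np.exp(-0.5 * ((idx - center) / sd) ** 2)
    s = w.sum()
    if s == 0:
        return np.zeros_like(w)
    return mass * w / s


def gen_fraction_profile(cfg: FractionSimConfig) -> tuple[pd.DataFrame, FractionTruth]:
    """Simulate a per-fraction measurement table for one gradient tube.

    Fluorescence is baseline + two discretized Gaussian peaks + Gaussian
    noise, clipped at zero.  Absorbance and refractive index are linear ramps
    across the tube (the gradient-linearity QC signal) plus small noise.
    """
    cfg.validate()
    rng = substream(cfg.seed, "fractions")
    idx = np.arange(1, cfg.n_fractions + 1)

    peak = _discrete_gaussian_mass(idx, cfg.peak_center, cfg.peak_sd, cfg.peak_mass)
    late = _discrete_gaussian_mass(idx, cfg.late_peak_center, cfg.late_peak_sd, cfg.late_peak_mass)
    fluor = cfg.baseline + peak + late + rng.normal(0.0, cfg.noise_sd, idx.size)
    fluor = np.clip(fluor, 0.0, None)

    # iodixanol 5% -> 30% across the tube: refractive index ~1.344 -> 1.384
    ri = np.linspace(1.344, 1.384, cfg.n_fractions) + rng.normal(0, 2e-4, idx.size)
    absorbance = np.linspace(0.05, 0.35, cfg.n_fractions) + rng.normal(0, 2e-3, idx.size)

    profile = pd.DataFrame(
        {
            "fraction_index": idx,
            "fluorescence": fluor,
            "absorbance": absorbance,
            "refractive_index": ri,
            "replicate_id": "sim",
        }
    )
    truth = FractionTruth(fraction_index=idx, peak_component=peak, late_component=late)
    return profile, truth


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------

def observed_to_population_cv(observed_median_cv: float, n_replicates: int) -> float:
    """Population CV whose n-replicate sample-CV *median* equals the target.

    The sample standard deviation of n replicates is distributed roughly as
    sigma * sqrt(chi2_{n-1} / (n-1)); its median therefore sits below sigma by
    the factor sqrt(median(chi2_{n-1}) / (n-1)) (0.833 for n=3).  Dividing an
    observed median CV by this factor recovers the generating population CV.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    factor = float(np.sqrt(stats.chi2.median(n_replicates - 1) / (n_replicates - 1)))
    return observed_median_cv / factor


def study_effect_structure(
    n_enriched: int = 39,
    n_depleted: int = 14,
    n_null: int = 3,
    seed: int = 0,
) -> dict[str, float]:
    """True log2 fold changes (LNP corona vs plasma control) for a simulation.

    Defaults mirror the study outcome: of 56 proteins shared between the LNP
    corona and the plasma-alone sample, 39 enriched, 14 depleted, 3 unchanged.
    Effect magnitudes are drawn once from ranges typical of the volcano plot
    (|log2FC| between 1.5 and 5).
    """
    rng = substream(seed, "proteome", "effects")
    fc: dict[str, float] = {}
    n_total = n_enriched + n_depleted + n_null
    width = max(4, len(str(n_total)))
    for i in range(n_total):
        acc = f"SIM{i:0{width}d}"
        if i < n_enriched:
            fc[acc] = float(rng.uniform(1.5, 5.0))
        elif i < n_enriched + n_depleted:
            fc[acc] = float(-rng.uniform(1.5, 4.0))
        else:
            fc[acc] = 0.0
    return fc


@dataclass
class ProteomeSimConfig:
    """Label-free peptide-intensity simulation for Hi3 quantification.

    Defaults are the study conditions: 56 shared proteins (39 enriched / 14
    depleted / 3 null), 3 technical replicates per condition, a 50 fmol ClpB
    (P63284) internal-standard spike, and technical-replicate noise whose
    observed n=3 median CV% matches the reported 11.8 (LNP) / 19.0 (plasma).
    """

    n_proteins: int = 56
    peptides_per_protein: int = 5
    true_log2fc: Mapping[str, float] | None = None
    base_abundance_fmol: Mapping[str, float] | None = None
    replicate_cv: float = observed_to_population_cv(0.118, 3)
    plasma_replicate_cv: float | None = observed_to_population_cv(0.190, 3)
    n_replicates: int = 3
    n_batches: int = 1
    spike_fmol: float = 50.0
    standard_accession: str = "P63284"
    seed: int = 0

    def validate(self) -> None:
        if self.peptides_per_protein < 1:
            raise ValueError("need >= 1 peptide per protein")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        if self.plasma_replicate_cv is not None and self.plasma_replicate_cv < 0:
            raise ValueError("plasma_replicate_cv must be >= 0")
        if self.spike_fmol <= 0:
            raise ValueError("spike_fmol must be > 0")
        if self.n_replicates < 1 or self.n_batches < 1:
            raise ValueError("replicate and batch counts must be >= 1")


@dataclass
class ProteomeTruth:
    """Ground truth accompanying a simulated peptide table."""

    true_log2fc: dict[str, float]
    base_abundance_fmol: dict[str, float]
    response_factors: dict[str, float]
    spike_fmol: float
    standard_accession: str

    def enriched_at(self, min_abs_log2fc: float = 0.0) -> set[str]:
        return {a for a, fc in self.true_log2fc.items() if fc > min_abs_log2fc}

    def depleted_at(self, min_abs_log2fc: float = 0.0) -> set[str]:
        return {a for a, fc in self.true_log2fc.items() if fc < -min_abs_log2fc}

    def to_dict(self) -> dict:
        return {
            "true_log2fc": self.true_log2fc,
            "base_abundance_fmol": self.base_abundance_fmol,
            "response_factors": self.response_factors,
            "spike_fmol": self.spike_fmol,
            "standard_accession": self.standard_accession,
        }


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def gen_peptide_table(cfg: ProteomeSimConfig) -> tuple[pd.DataFrame, ProteomeTruth]:
    """Simulate a tidy peptide-intensity table (both conditions, all runs).

    Per peptide, intensity = protein abundance (fmol) x peptide response
    factor x log-normal replicate noise with the configured CV (unit mean).
    Plasma abundance = LNP abundance / 2**true_log2fc.  The internal-standard
    protein is present at ``spike_fmol`` in every run with zero fold change.
    Response factors are drawn once per peptide from log-uniform [0.2, 5] so
    that top-3 peptide selection is nontrivial.
    """
    cfg.validate()
    rng_truth = substream(cfg.seed, "proteome", "truth")
    rng_noise = substream(cfg.seed, "proteome", "noise")

    fc_map = dict(cfg.true_log2fc) if cfg.true_log2fc is not None else study_effect_structure(
        seed=cfg.seed
    )
    accessions = list(fc_map)[: cfg.n_proteins]
    if cfg.true_log2fc is None and len(accessions) < cfg.n_proteins:
        raise ValueError("default effect structure smaller than n_proteins")
    fc_map = {a: fc_map[a] for a in accessions}

    if cfg.base_abundance_fmol is not None:
        base = {a: float(cfg.base_abundance_fmol[a]) for a in accessions}
    else:
        base = {
            a: float(np.exp(rng_truth.uniform(np.log(5.0), np.log(500.0))))
            for a in accessions
        }

    all_accessions = accessions + [cfg.standard_accession]
    fc_map_full = dict(fc_map)
    fc_map_full[cfg.standard_accession] = 0.0
    base_full = dict(base)
    base_full[cfg.standard_accession] = cfg.spike_fmol

    response: dict[str, float] = {}
    for acc in all_accessions:
        for j in range(cfg.peptides_per_protein):
            pep = f"{acc}_pep{j:02d}"
            response[pep] = float(
                np.exp(rng_truth.uniform(np.log(0.2), np.log(5.0)))
            )

    cv_by_condition = {
        "LNP": cfg.replicate_cv,
        "PLASMA": cfg.plasma_replicate_cv
        if cfg.plasma_replicate_cv is not None
        else cfg.replicate_cv,
    }

    rows: list[tuple] = []
    for batch in range(1, cfg.n_batches + 1):
        for condition in ("LNP", "PLASMA"):
            sigma = _lognormal_sigma(cv_by_condition[condition])
            for rep in range(1, cfg.n_replicates + 1):
                for acc in all_accessions:
                    abundance = base_full[acc]
                    if condition == "PLASMA":
                        abundance = abundance / 2.0 ** fc_map_full[acc]
                    for j in range(cfg.peptides_per_protein):
                        pep = f"{acc}_pep{j:02d}"
                        if sigma > 0:
                            noise = np.exp(rng_noise.normal(-0.5 * sigma**2, sigma))
                        else:
                            noise = 1.0
                        intensity = (
                            abundance * response[pep] * INTENSITY_PER_FMOL * noise
                        )
                        rows.append(
                            (pep, acc, condition, f"rep{rep}", f"batch{batch}", intensity)
                        )

    table = pd.DataFrame(
        rows,
        columns=[
            "peptide_id",
            "protein_accession",
            "condition",
            "replicate_id",
            "batch_id",
            "intensity",
        ],
    )
    truth = ProteomeTruth(
        true_log2fc=fc_map_full,
        base_abundance_fmol=base_full,
        response_factors=response,
        spike_fmol=cfg.spike_fmol,
        standard_accession=cfg.standard_accession,
    )
    return table, truth


# ---------------------------------------------------------------------------
# microscopy fields of view
# ---------------------------------------------------------------------------

@dataclass
class ImageFOV:
    """One multi-channel field of view plus acquisition metadata."""

    channels: dict[str, np.ndarray]
    pixel_size: float = 0.4  # um / px
    condition: str = "sim"
    biological_replicate: str = "bio1"
    technical_replicate: str = "tech1"
    fov_index: int = 0


@dataclass
class FovSimConfig:
    """Synthetic field-of-view geometry and noise.

    Cells are non-overlapping disks (cytoplasmic membrane stain) with a
    bright nuclear disk; Cy5 puncta are placed per compartment — inner
    (survives ``rim_width``-fold 3x3 erosion of the cell mask), outer (the rim
    band), or lysosomal (on LysoTracker-style vesicles in the inner region) —
    then blurred by a Gaussian PSF with Poisson-approximating Gaussian noise.
    ``rim_width`` defaults to 10 to match the 10-fold erosion analysis.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_cells: int = 6
    nucleus_radius: float = 7.0
    cell_radius: float = 26.0
    puncta_per_cell_inner: float = 6.0
    puncta_per_cell_outer: float = 2.0
    puncta_per_cell_lyso: float = 3.0
    lysosomes_per_cell: int = 5
    lysosome_radius: float = 3.0
    rim_width: int = 10
    placement_margin_px: int = 2
    psf_sigma: float = 0.8
    punctum_amplitude: float = 2000.0
    photon_noise_scale: float = 1.0
    background: float = 0.2
    nucleus_amplitude: float = 200.0
    cell_amplitude: float = 120.0
    lysosome_amplitude: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        if self.cell_radius <= self.nucleus_radius:
            raise ValueError("cell_radius must exceed nucleus_radius")
        for r in (
            self.puncta_per_cell_inner,
            self.puncta_per_cell_outer,
            self.puncta_per_cell_lyso,
        ):
            if r < 0:
                raise ValueError("puncta rates must be >= 0")
        if self.n_cells < 1:
            raise ValueError("need >= 1 cell")
        if self.rim_width < 1:
            raise ValueError("rim_width must be >= 1")
        if min(self.image_shape) < 2 * self.cell_radius + 8:
            raise ValueError("image too small for the configured cell radius")


@dataclass
class FovTruth:
    """Exact placements and per-compartment signal of a simulated FOV."""

    nuclei_count: int
    counts: dict[str, int]  # inner / outer / lyso punctum counts
    placements: dict[str, list[tuple[int, int]]]
    amplitude: float
    background: float

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def true_signal_per_cell(self) -> float:
        return self.total_count * self.amplitude / self.nuclei_count

    @property
    def true_outer_fraction(self) -> float:
        return self.counts["outer"] / max(self.total_count, 1)

    @property
    def true_coloc_per_cell(self) -> float:
        return self.counts["lyso"] * self.amplitude / self.nuclei_count

    def to_dict(self) -> dict:
        return {
            "nuclei_count": self.nuclei_count,
            "counts": self.counts,
            "placements": {k: [list(p) for p in v] for k, v in self.placements.items()},
            "amplitude": self.amplitude,
            "background": self.background,
            "true_signal_per_cell": self.true_signal_per_cell,
            "true_outer_fraction": self.true_outer_fraction,
            "true_coloc_per_cell": self.true_coloc_per_cell,
        }


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _place_cells(cfg: FovSimConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    margin = cfg.cell_radius + 3
    min_sep2 = (2 * cfg.cell_radius + 3) ** 2
    centers: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(centers) == cfg.n_cells:
            break
        r = rng.uniform(margin, cfg.image_shape[0] - margin)
        c = rng.uniform(margin, cfg.image_shape[1] - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep2 for r0, c0 in centers):
            centers.append((r, c))
    if len(centers) < cfg.n_cells:
        raise ValueError(
            f"could not place {cfg.n_cells} non-overlapping cells of radius "
            f"{cfg.cell_radius} in a {cfg.image_shape} image"
        )
    return centers


def _noisy(img: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    if scale <= 0:
        return img
    noisy = img + rng.normal(0.0, scale * np.sqrt(np.clip(img, 0, None) + 1e-9), img.shape)
    return np.clip(noisy, 0.0, None)


def gen_fov(cfg: FovSimConfig, fov_index: int = 0) -> tuple[ImageFOV, FovTruth]:
    """Simulate one field of view with nuclei, membrane, lysosome, Cy5 channels.

    The "inner" compartment is defined by the same morphological rule the
    analysis applies (``rim_width``-fold erosion with a full 3x3 element), so
    the recorded outer-fraction truth is directly comparable to the measured
    one.  Blur conserves total punctum signal (cells sit away from borders).
    """
    cfg.validate()
    rng = substream(cfg.seed, "fov", str(fov_index))
    shape = tuple(cfg.image_shape)
    centers = _place_cells(cfg, rng)

    membrane = np.zeros(shape, dtype=bool)
    nuclei = np.zeros(shape, dtype=float)
    cell_masks: list[np.ndarray] = []
    for ctr in centers:
        m = _disk_mask(shape, ctr, cfg.cell_radius)
        cell_masks.append(m)
        membrane |= m
        nuclei[_disk_mask(shape, ctr, cfg.nucleus_radius)] = cfg.nucleus_amplitude

    inner = ndimage.binary_erosion(
        membrane, structure=np.ones((3, 3), bool), iterations=cfg.rim_width
    )
    outer = membrane & ~inner

    # lysosomes: small vesicles inside the inner region of each cell
    lysosome_channel = np.zeros(shape, dtype=float)
    lysosome_centers: list[tuple[int, int]] = []
    for m in cell_masks:
        candidates = np.argwhere(m & inner)
        if candidates.size == 0:
            if cfg.puncta_per_cell_lyso > 0 or cfg.lysosomes_per_cell > 0:
                raise ValueError(
                    "inner region empty after erosion; cannot place lysosomes "
                    "(increase cell_radius or decrease rim_width)"
                )
            continue
        take = rng.choice(len(candidates), size=cfg.lysosomes_per_cell, replace=True)
        for k in take:
            r, c = map(int, candidates[k])
            lysosome_centers.append((r, c))
            lysosome_channel[_disk_mask(shape, (r, c), cfg.lysosome_radius)] = (
                cfg.lysosome_amplitude
            )

    cy5 = np.zeros(shape, dtype=float)
    placements: dict[str, list[tuple[int, int]]] = {"inner": [], "outer": [], "lyso": []}
    per_cell_lysos = np.array_split(np.arange(len(lysosome_centers)), len(cell_masks))
    lyso_footprint = lysosome_channel > 0

    def _with_margin(mask: np.ndarray) -> np.ndarray:
        # keep puncta away from compartment boundaries so that the placement
        # compartment stays unambiguous under the PSF blur; fall back to the
        # full compartment when the margin would empty it
        if cfg.placement_margin_px <= 0:
            return mask
        shrunk = ndimage.binary_erosion(
            mask, np.ones((3, 3), bool), iterations=cfg.placement_margin_px
        )
        return shrunk if shrunk.any() else mask

    for ci, m in enumerate(cell_masks):
        # inner puncta also avoid the lysosome footprint so chance overlap does
        # not blur the distinction between inner and lysosomal compartments
        compartment_pixels = {
            "inner": np.argwhere(_with_margin(m & inner) & ~lyso_footprint),
            "outer": np.argwhere(_with_margin(m & outer)),
        }
        for comp, rate in (
            ("inner", cfg.puncta_per_cell_inner),
            ("outer", cfg.puncta_per_cell_outer),
        ):
            n = int(rng.poisson(rate))
            pix = compartment_pixels[comp]
            if n > 0 and len(pix) == 0:
                raise ValueError(
                    f"no pixels available in the '{comp}' compartment for the "
                    "configured geometry"
                )
            for k in rng.choice(len(pix), size=n, replace=True) if n else []:
                r, c = map(int, pix[k])
                cy5[r, c] += cfg.punctum_amplitude
                placements[comp].append((r, c))
        n_lyso = int(rng.poisson(cfg.puncta_per_cell_lyso))
        own = per_cell_lysos[ci]
        if n_lyso > 0 and len(own) == 0:
            raise ValueError("no lysosomes available for lysosomal puncta")
        for k in rng.choice(own, size=n_lyso, replace=True) if n_lyso else []:
            r, c = lysosome_centers[int(k)]
            cy5[r, c] += cfg.punctum_amplitude
            placements["lyso"].append((r, c))

    membrane_channel = np.where(membrane, cfg.cell_amplitude, 0.0)
    channels = {}
    for name, raw in (
        ("nuclei", nuclei),
        ("membrane", membrane_channel),
        ("lysosome", lysosome_channel),
        ("cy5", cy5),
    ):
        img = ndimage.gaussian_filter(raw, cfg.psf_sigma) + cfg.background
        channels[name] = _noisy(img, cfg.photon_noise_scale, rng)

    fov = ImageFOV(channels=channels, fov_index=fov_index)
    truth = FovTruth(
        nuclei_count=cfg.n_cells,
        counts={k: len(v) for k, v in placements.items()},
        placements=placements,
        amplitude=cfg.punctum_amplitude,
        background=cfg.background,
    )
    return fov, truth


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------

@dataclass
class FlowTruth:
    """Analytic truth for a simulated control/treated flow pair."""

    control_mean: float
    control_sd: float
    treated_shift: float

    def true_pct_positive(self, gate_quantile: float = 0.995) -> float:
        """Exact percent of treated events above the population control gate."""
        thr = self.control_mean + self.control_sd * stats.norm.ppf(gate_quantile)
        z = (thr - (self.control_mean + self.treated_shift)) / self.control_sd
        return 100.0 * float(stats.norm.sf(z))

    def to_dict(self) -> dict:
        return {
            "control_mean": self.control_mean,
            "control_sd": self.control_sd,
            "treated_shift": self.treated_shift,
            "true_pct_positive_q0.995": self.true_pct_positive(0.995),
        }


def gen_flow_sample(
    n_events: int = 10000,
    control_mean: float = 100.0,
    control_sd: float = 15.0,
    treated_shift: float = 45.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, FlowTruth]:
    """Simulate per-event Cy5 intensities for a non-treated control and a
    treated sample whose population is shifted by ``treated_shift``."""
    if n_events < 1000:
        raise ValueError("n_events must be >= 1000")
    if control_sd <= 0:
        raise ValueError("control_sd must be > 0")
    rng = substream(seed, "flow")
    control = rng.normal(control_mean, control_sd, n_events)
    treated = rng.normal(control_mean + treated_shift, control_sd, n_events)
    truth = FlowTruth(control_mean, control_sd, treated_shift)
    return control, treated, truth
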
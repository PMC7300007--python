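"""Synthetic cohort generator for the targeted-MS checkpoint panel pipeline.

Every downstream stage (PRM quantification, cohort association, proteotype
enrichment) can be exercised against data with known ground truth.  The
generator emulates:

* per-target protein abundance (fmol/ug tissue protein) drawn log-normal,
  spanning the orders of magnitude typical of immune-checkpoint proteins in
  FFPE tumor lysates;
* mRNA abundance (RPM) as a log-scale bivariate normal with a configurable
  squared correlation to protein, per target;
* PD-L1 tumor proportion score (TPS, percent of stained tumor cells) as a
  saturating logistic transform of PD-L1 abundance plus noise, clipped to
  [0, 100] and rounded to integer percent;
* tumor mutation burden (mutations/Mb) log-normal and independent of every
  target, spanning roughly two hundred-fold;
* light/heavy transition-level peak areas for a stable-isotope-dilution PRM
  assay (heavy standard spiked at a known fmol amount into a known mass of
  digested protein), with multiplicative area noise, mass-error spread,
  interference corruption and a detection floor;
* a spectral-count matrix (background proteome x samples) with
  negative-binomial counts in which the members of one gene set shift with a
  chosen target's abundance, plus a GMT-writable gene-set collection.

All randomness flows from ``SyntheticConfig.seed`` through
``numpy.random.default_rng``; identical configs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PANEL",
    "DEFAULT_MRNA_R2",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_transitions",
    "generate_spectral_counts",
]

#: The ten-protein immune-checkpoint drug-target panel.
DEFAULT_PANEL: tuple[str, ...] = (
    "PD-1",
    "PD-L1",
    "PD-L2",
    "IDO1",
    "LAG3",
    "TIM3",
    "ICOSLG",
    "VISTA",
    "GITR",
    "CD40",
)

#: Default per-target squared protein-mRNA correlation (log scale).  PD-1,
#: PD-L1 and IDO1 show appreciable correlation in NSCLC cohorts; the other
#: checkpoint targets show essentially none.
DEFAULT_MRNA_R2: dict[str, float] = {
    "PD-1": 0.17,
    "PD-L1": 0.70,
    "IDO1": 0.74,
}
_MRNA_R2_OTHER = 0.05

TRANSITION_COLUMNS = [
    "sample_id",
    "protein_id",
    "peptide_seq",
    "fragment_id",
    "label",
    "area",
    "mass_error_ppm",
    "rt_apex",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Units: abundances fmol/ug, spike fmol, protein input ug, RT minutes,
    mass error ppm, TPS percent, TMB mutations/Mb.
    """

    n_samples: int = 46
    target_names: tuple[str, ...] = DEFAULT_PANEL
    spike_fmol: float = 50.0
    protein_input_ug: float = 100.0
    n_transitions_per_peptide: int = 5
    area_cv: float = 0.10
    ppm_sd: float = 1.5
    interference_rate: float = 0.02
    detection_floor_fmol_per_ug: float = 0.05
    protein_mrna_r2: Mapping[str, float] | float | None = None
    tps_noise_sd: float = 25.0
    n_background_proteins: int = 300
    gene_set_effect: float = 1.0
    n_gene_sets: int = 8
    gene_set_size: int = 30
    nb_dispersion: float = 0.3
    library_size_range: tuple[float, float] = (40_000.0, 80_000.0)
    gsea_target: str = "PD-L1"
    abundance_log_mean: float = math.log(0.2)
    abundance_log_sd: float = 1.0
    mrna_log_mean: float = math.log(8.0)
    mrna_log_sd: float = 1.0
    tmb_log_mean: float = math.log(5.0)
    tmb_log_sd: float = 1.2
    rt_coelute_tol: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.target_names:
            raise ValueError("target_names must be non-empty")
        if self.spike_fmol <= 0:
            raise ValueError("spike_fmol must be > 0")
        if self.protein_input_ug <= 0:
            raise ValueError("protein_input_ug must be > 0")
        if self.n_transitions_per_peptide < 1:
            raise ValueError("n_transitions_per_peptide must be >= 1")
        if self.n_background_proteins < 1:
            raise ValueError("n_background_proteins must be >= 1")
        if self.n_gene_sets < 1 or self.gene_set_size < 1:
            raise ValueError("gene-set counts must be >= 1")
        for name, rate in [("interference_rate", self.interference_rate)]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name, val in [
            ("area_cv", self.area_cv),
            ("ppm_sd", self.ppm_sd),
            ("tps_noise_sd", self.tps_noise_sd),
            ("nb_dispersion", self.nb_dispersion),
            ("detection_floor_fmol_per_ug", self.detection_floor_fmol_per_ug),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        for r2 in self._r2_map().values():
            if not 0.0 <= r2 <= 1.0:
                raise ValueError("protein_mrna_r2 values must lie in [0, 1]")
        if self.gsea_target not in self.target_names:
            raise ValueError(f"gsea_target {self.gsea_target!r} not in target_names")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must satisfy 0 < low <= high")

    def _r2_map(self) -> dict[str, float]:
        """Resolve protein_mrna_r2 to a per-target dict."""
        if self.protein_mrna_r2 is None:
            return {
                t: DEFAULT_MRNA_R2.get(t, _MRNA_R2_OTHER) for t in self.target_names
            }
        if isinstance(self.protein_mrna_r2, (int, float)):
            return {t: float(self.protein_mrna_r2) for t in self.target_names}
        out = dict(self.protein_mrna_r2)
        missing = set(self.target_names) - set(out)
        if missing:
            raise ValueError(f"protein_mrna_r2 missing targets: {sorted(missing)}")
        return {t: float(out[t]) for t in self.target_names}

    def with_(self, **kwargs) -> "SyntheticConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic cohort.

    ``true_abundance`` and ``true_mrna`` are targets x samples DataFrames
    (fmol/ug and RPM respectively); ``set_membership`` maps gene-set name to
    its member protein identifiers.
    """

    true_abundance: pd.DataFrame
    true_mrna: pd.DataFrame
    set_membership: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def detected_mask(self, floor: float) -> pd.DataFrame:
        """Boolean targets x samples mask of abundances at or above *floor*."""
        return self.true_abundance >= floor


def _sanitize(name: str) -> str:
    return "".join(ch for ch in name.upper() if ch.isalnum())


def peptide_for_target(target: str) -> str:
    """Deterministic synthetic signature-peptide identifier for a target."""
    return f"{_sanitize(target)}SIGPEPK"


def generate_cohort(config: SyntheticConfig) -> tuple[SyntheticTruth, pd.DataFrame]:
    """Generate ground-truth abundances and the joined cohort metadata table.

    Returns ``(truth, cohort)`` where *cohort* has one row per sample with
    columns ``sample_id``, ``histology``, per-target ``{t}_fmol_per_ug`` and
    ``{t}_status`` (true abundance censored at the detection floor),
    per-target ``{t}_mrna_rpm``, ``tps_percent`` and ``tmb_mut_per_mb``.

    Protein and mRNA are jointly log-normal per target: with ``r2`` the
    configured squared correlation, ``log mRNA`` shares a standard-normal
    component with ``log protein`` weighted ``sqrt(r2)``, so the population
    squared correlation on the log scale is exactly ``r2``.
    """
    if config.n_samples < 3:
        raise ValueError(
            "n_samples must be >= 3: downstream correlations are undefined"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    targets = list(config.target_names)
    samples = [f"S{i + 1:03d}" for i in range(n)]
    r2_map = config._r2_map()

    z_prot = rng.standard_normal((len(targets), n))
    z_ind = rng.standard_normal((len(targets), n))
    abundance = np.exp(config.abundance_log_mean + config.abundance_log_sd * z_prot)
    r = np.sqrt([r2_map[t] for t in targets])[:, None]
    z_mrna = r * z_prot + np.sqrt(1.0 - r**2) * z_ind
    mrna = np.exp(config.mrna_log_mean + config.mrna_log_sd * z_mrna)

    true_abundance = pd.DataFrame(abundance, index=targets, columns=samples)
    true_mrna = pd.DataFrame(mrna, index=targets, columns=samples)
    truth = SyntheticTruth(
        true_abundance=true_abundance, true_mrna=true_mrna, seed=config.seed
    )

    cohort = pd.DataFrame({"sample_id": samples})
    cohort["histology"] = rng.choice(
        ["adenocarcinoma", "squamous cell carcinoma"], size=n
    )
    floor = config.detection_floor_fmol_per_ug
    for t in targets:
        a = true_abundance.loc[t].to_numpy()
        observed = np.where(a >= floor, a, 0.0)
        cohort[f"{t}_fmol_per_ug"] = observed
        cohort[f"{t}_status"] = np.where(a >= floor, "detected", "zero_assigned")
        cohort[f"{t}_mrna_rpm"] = true_mrna.loc[t].to_numpy()

    # TPS: logistic saturation of PD-L1 abundance (midpoint 0.35 fmol/ug on
    # the log scale) plus additive percent-scale noise, clipped and rounded.
    pdl1 = targets[0] if "PD-L1" not in targets else "PD-L1"
    log_a = np.log(true_abundance.loc[pdl1].to_numpy())
    tps_clean = 100.0 / (1.0 + np.exp(-(log_a - math.log(0.35)) / 0.5))
    tps = tps_clean + rng.normal(0.0, config.tps_noise_sd, size=n)
    cohort["tps_percent"] = np.clip(np.rint(tps), 0, 100).astype(int)

    cohort["tmb_mut_per_mb"] = np.exp(
        config.tmb_log_mean + config.tmb_log_sd * rng.standard_normal(n)
    )
    return truth, cohort


def generate_transitions(
    truth: SyntheticTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Generate light/heavy transition peak areas for the whole cohort.

    One signature peptide per target with ``n_transitions_per_peptide``
    fragment ions.  Per-fragment response factors are drawn once and shared
    by both label channels, so at zero noise light/heavy = true amount /
    spike exactly.  Heavy areas are ``rf * spike_fmol``; light areas are
    ``rf * abundance * protein_input_ug`` (the fmol of endogenous peptide on
    column), each perturbed by log-normal noise of coefficient of variation
    ``area_cv``.

    Interference corrupts a light transition with probability
    ``interference_rate``: with equal probability its mass error is pushed
    beyond 5 ppm, or its retention time is shifted out of co-elution and its
    area distorted (a discordant light/heavy ratio).  Either mode makes the
    transition fail quantification QC deterministically.

    Below the detection floor the light channel emits a single transition,
    emulating sporadic endogenous signal too weak for confident detection.
    """
    rng = np.random.default_rng(_child_seed(config.seed, 1))
    targets = list(truth.true_abundance.index)
    samples = list(truth.true_abundance.columns)
    n_frag = config.n_transitions_per_peptide
    fragments = [f"y{j + 3:02d}" for j in range(n_frag)]

    # Per (target, fragment) response factor and per-target retention time,
    # fixed across samples.
    rf = np.exp(rng.normal(math.log(2.0e4), 0.8, size=(len(targets), n_frag)))
    rt_base = rng.uniform(10.0, 40.0, size=len(targets))

    def area_noise(size) -> np.ndarray:
        if config.area_cv == 0:
            return np.ones(size)
        sigma = math.sqrt(math.log(1.0 + config.area_cv**2))
        return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))

    rows: list[tuple] = []
    floor = config.detection_floor_fmol_per_ug
    rt_jitter_sd = config.rt_coelute_tol / 10.0
    for ti, target in enumerate(targets):
        peptide = peptide_for_target(target)
        for sample in samples:
            a = truth.true_abundance.at[target, sample]
            light_fmol = a * config.protein_input_ug
            heavy = rf[ti] * config.spike_fmol * area_noise(n_frag)
            light = rf[ti] * light_fmol * area_noise(n_frag)
            ppm_h = rng.normal(0.0, config.ppm_sd, n_frag) if config.ppm_sd else np.zeros(n_frag)
            ppm_l = rng.normal(0.0, config.ppm_sd, n_frag) if config.ppm_sd else np.zeros(n_frag)
            rt_h = rt_base[ti] + (
                rng.normal(0.0, rt_jitter_sd, n_frag) if rt_jitter_sd else 0.0
            )
            rt_l = rt_base[ti] + (
                rng.normal(0.0, rt_jitter_sd, n_frag) if rt_jitter_sd else 0.0
            )

            corrupt = rng.random(n_frag) < config.interference_rate
            ppm_mode = rng.random(n_frag) < 0.5
            for j in np.nonzero(corrupt & ppm_mode)[0]:
                ppm_l[j] = rng.choice([-1.0, 1.0]) * rng.uniform(6.0, 20.0)
            for j in np.nonzero(corrupt & ~ppm_mode)[0]:
                rt_l[j] += rng.choice([-1.0, 1.0]) * config.rt_coelute_tol * rng.uniform(
                    2.0, 10.0
                )
                light[j] *= 10.0 ** (rng.choice([-1.0, 1.0]) * rng.uniform(0.7, 1.5))

            if a < floor:
                keep_light = [int(np.argmax(rf[ti]))]
            else:
                keep_light = list(range(n_frag))

            for j in range(n_frag):
                rows.append(
                    (sample, target, peptide, fragments[j], "heavy",
                     heavy[j], ppm_h[j], rt_h[j])
                )
            for j in keep_light:
                rows.append(
                    (sample, target, peptide, fragments[j], "light",
                     light[j], ppm_l[j], rt_l[j])
                )

    return pd.DataFrame(rows, columns=TRANSITION_COLUMNS)


def generate_spectral_counts(
    truth: SyntheticTruth, config: SyntheticConfig
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Generate a background-proteome spectral-count matrix and gene sets.

    Counts are gamma-Poisson (negative binomial, dispersion
    ``nb_dispersion``) with per-sample library sizes and log-normal
    per-protein base rates.  One "signal" set, named after
    ``config.gsea_target``, has its members' log-means shifted by
    ``gene_set_effect * z(target)`` where ``z`` is the standardized log true
    abundance of the target across samples; the remaining sets are null.
    Gene sets are mutually disjoint samples of the background proteome.

    Returns ``(counts, gene_sets)`` with *counts* a proteins x samples
    integer DataFrame.  ``truth.set_membership`` is updated in place.
    """
    total_members = config.n_gene_sets * config.gene_set_size
    if config.gene_set_size > config.n_background_proteins:
        raise ValueError("gene_set_size exceeds n_background_proteins")
    if total_members > config.n_background_proteins:
        raise ValueError(
            "gene sets require more member proteins than the background proteome"
        )
    rng = np.random.default_rng(_child_seed(config.seed, 2))
    n = truth.true_abundance.shape[1]
    samples = list(truth.true_abundance.columns)
    proteins = [f"BG{i + 1:04d}" for i in range(config.n_background_proteins)]

    member_pool = rng.permutation(config.n_background_proteins)[:total_members]
    gene_sets: dict[str, list[str]] = {}
    for k in range(config.n_gene_sets):
        idx = member_pool[k * config.gene_set_size : (k + 1) * config.gene_set_size]
        members = sorted(proteins[i] for i in idx)
        name = (
            f"RESPONSE_{_sanitize(config.gsea_target)}"
            if k == 0
            else f"NULL_SET_{k:02d}"
        )
        gene_sets[name] = members

    log_a = np.log(truth.true_abundance.loc[config.gsea_target].to_numpy())
    z_t = (log_a - log_a.mean()) / log_a.std(ddof=0) if log_a.std(ddof=0) > 0 else np.zeros(n)

    base = np.exp(rng.normal(0.0, 1.0, size=config.n_background_proteins))
    base /= base.sum()
    lib = rng.uniform(*config.library_size_range, size=n)
    shift = np.zeros((config.n_background_proteins, n))
    signal_name = next(iter(gene_sets))
    signal_idx = [proteins.index(p) for p in gene_sets[signal_name]]
    shift[signal_idx, :] = config.gene_set_effect * z_t[None, :]

    mu = base[:, None] * lib[None, :] * np.exp(shift)
    if config.nb_dispersion > 0:
        lam = rng.gamma(
            shape=1.0 / config.nb_dispersion, scale=mu * config.nb_dispersion
        )
    else:
        lam = mu
    counts = rng.poisson(lam)

    truth.set_membership = {k: list(v) for k, v in gene_sets.items()}
    out = pd.DataFrame(counts, index=proteins, columns=samples)
    out.index.name = "protein_id"
    return out, gene_sets


def _child_seed(seed: int, stream: int) -> int:
    """Derive a deterministic sub-seed below 2**31 for an internal stream."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))
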
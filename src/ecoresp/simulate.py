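"""Multi-cohort synthetic OGU table generator with known ground truth.

The generator emulates the statistical structure of a multi-study stool
metagenome collection in an immunotherapy setting: eleven cohorts of
unequal size, extreme zero sparsity driven by a heavy-tailed occupancy
distribution, dataset-level compositional shifts, planted log-scale
response effects positively rank-correlated with occupancy, and a minority
of low-occupancy "allochthonous" taxa (oral/food flagged) that are shifted
toward non-responders.

Generative model, per sample ``s`` in dataset ``d`` with response ``x``:

1. per-OGU baseline log-abundance  ``mu_j ~ N(0, baseline_log_sd)``;
2. per-OGU occupancy probability ``q_j`` from a Beta(prevalence_shape)
   draw rescaled so that ``mean(q) = 1 - target_sparsity`` (structural
   zeros);
3. planted effects ``e_j`` drawn jointly with occupancy through a Gaussian
   copula whose latent correlation ``2 sin(pi * rho / 6)`` targets a
   Spearman correlation of ``prevalence_effect_rho`` between occupancy and
   effect;
4. composition ``p_s = softmax(mu + a_d + e * 1[x = R] + eps_s)`` masked by
   per-(sample, OGU) Bernoulli(q) occupancy draws, counts multinomial at a
   lognormal depth;
5. a ``frac_allochthonous`` subset of low-occupancy OGUs is flagged
   oral/food and receives an additional NR-direction shift;
6. gene-family sets are assigned so a designated family subset is enriched
   among true R-marker genomes.

All randomness flows through named substreams spawned from the single
config seed, so a fixed seed gives bit-identical output and changing one
dimension does not perturb the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .core_io import OguCountTable, OguMetadata, SampleMetadata

#: substream order is part of the determinism contract
_STREAMS = (
    "copula",
    "baseline",
    "intercepts",
    "labels",
    "depths",
    "occupancy_draws",
    "noise",
    "flags",
    "families",
    "quality",
)

#: per-dataset sample counts of the emulated 11-cohort collection
_DEFAULT_SIZES = (39, 22, 38, 134, 164, 27, 29, 40, 14, 11, 106)
_DEFAULT_CANCER = ("melanoma",) * 7 + ("other",) * 4

_PHYLA = (
    ("Firmicutes", 0.666),
    ("Actinobacteriota", 0.169),
    ("Bacteroidota", 0.105),
    ("Proteobacteria", 0.037),
    ("Verrucomicrobiota", 0.023),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults for the synthetic cohort collection.

    ``samples_per_dataset`` may be a single int (replicated) or one size per
    dataset; the default mirrors an 11-cohort, 624-sample collection with a
    72.7% melanoma share.
    """

    seed: int
    n_datasets: int = 11
    samples_per_dataset: int | Sequence[int] = _DEFAULT_SIZES
    n_ogus: int = 2000
    depth_log_mean: float = 9.0
    depth_log_sd: float = 1.0
    target_sparsity: float = 0.96
    prevalence_shape: tuple[float, float] = (0.3, 3.0)
    baseline_log_sd: float = 2.0
    noise_log_sd: float = 0.5
    effect_sd: float = 1.0
    prevalence_effect_rho: float = 0.25
    dataset_intercept_sd: float = 1.0
    frac_allochthonous: float = 0.096
    allochthonous_nr_shift: float = 0.5
    response_balance: float = 0.582
    marker_cutoff_multiple: float = 2.0
    dataset_cancer: Sequence[str] = _DEFAULT_CANCER
    n_gene_families: int = 60
    n_enriched_families: int = 15
    family_base_rate: float = 0.25
    family_enriched_rate: float = 0.6

    def sizes(self) -> tuple[int, ...]:
        if isinstance(self.samples_per_dataset, int):
            return (self.samples_per_dataset,) * self.n_datasets
        sizes = tuple(int(s) for s in self.samples_per_dataset)
        if len(sizes) != self.n_datasets:
            raise ValueError(
                f"samples_per_dataset has {len(sizes)} entries for "
                f"{self.n_datasets} datasets"
            )
        return sizes

    def cancers(self) -> tuple[str, ...]:
        c = tuple(self.dataset_cancer)
        if len(c) == self.n_datasets:
            return c
        if len(c) == len(_DEFAULT_CANCER):
            # default labels with a non-default dataset count: split ~70/30
            n_mel = max(1, round(0.7 * self.n_datasets))
            return ("melanoma",) * n_mel + ("other",) * (self.n_datasets - n_mel)
        raise ValueError("dataset_cancer length does not match n_datasets")

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")
        for name in ("target_sparsity", "frac_allochthonous", "response_balance"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if self.n_datasets < 1 or self.n_ogus < 2 or min(self.sizes()) < 2:
            raise ValueError("counts must be positive (>=2 samples, >=2 OGUs)")
        if not -1.0 < self.prevalence_effect_rho < 1.0:
            raise ValueError("prevalence_effect_rho must lie in (-1, 1)")
        if self.effect_sd < 0 or self.dataset_intercept_sd < 0:
            raise ValueError("scale parameters must be non-negative")
        expected_occupied = (1.0 - self.target_sparsity) * self.n_ogus
        if expected_occupied < 1.0:
            raise ValueError(
                "infeasible: target_sparsity leaves < 1 occupied OGU per sample"
            )
        if np.exp(self.depth_log_mean) < 10 * expected_occupied:
            raise ValueError(
                "infeasible: sequencing depth too shallow to realize the "
                "target sparsity (sampling zeros would dominate)"
            )


@dataclass
class SimTruth:
    """Full ground truth of a simulated cohort collection."""

    planted_effect: np.ndarray  # total per-OGU log-scale R-vs-NR shift
    effect_base: np.ndarray  # copula component, before the allochthonous shift
    true_marker_label: list[str]  # per-OGU in {"R", "NR", "null"}
    marker_cutoff: float
    dataset_intercepts: np.ndarray  # (n_datasets, n_ogus) compositional shifts
    occupancy: np.ndarray  # per-OGU inclusion probability
    source_flags: list[list[str]]
    enriched_families: list[str]
    depths: np.ndarray  # per-sample multinomial depth
    seeds: dict[str, int]

    def marker_ids(self, ogu_ids: Sequence[str], label: str) -> set[str]:
        return {o for o, lab in zip(ogu_ids, self.true_marker_label) if lab == label}


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.Generator(np.random.PCG64(c)) for name, c in zip(_STREAMS, children)}


def _occupancy_and_effects(cfg: SimConfig, rng: np.random.Generator):
    """Joint draw of occupancy probabilities and base effects (Gaussian copula)."""
    rho = cfg.prevalence_effect_rho
    latent_r = 2.0 * np.sin(np.pi * rho / 6.0)  # Spearman -> latent Pearson
    z = rng.standard_normal((cfg.n_ogus, 2))
    z_occ = z[:, 0]
    z_eff = latent_r * z[:, 0] + np.sqrt(1.0 - latent_r**2) * z[:, 1]
    a, b = cfg.prevalence_shape
    raw = _sps.beta.ppf(_sps.norm.cdf(z_occ), a, b)
    raw = np.clip(raw, 1e-12, 1.0)
    target = 1.0 - cfg.target_sparsity
    scale = target / raw.mean()
    occ = np.clip(raw * scale, 0.0, 1.0)
    for _ in range(50):  # fixed-point rescale when clipping at 1 bites
        m = occ.mean()
        if abs(m - target) < 1e-9:
            break
        scale *= target / m
        occ = np.clip(raw * scale, 0.0, 1.0)
    effects = cfg.effect_sd * z_eff
    return occ, effects


def simulate_cohorts(
    config: SimConfig,
) -> tuple[OguCountTable, dict[str, SampleMetadata], dict[str, OguMetadata], SimTruth]:
    """Generate counts, sample metadata, OGU metadata and ground truth."""
    cfg = config
    cfg.validate()
    rng = _streams(cfg.seed)
    sizes = cfg.sizes()
    cancers = cfg.cancers()
    n_total = sum(sizes)
    n_ogus = cfg.n_ogus

    occupancy, effect_base = _occupancy_and_effects(cfg, rng["copula"])
    baseline = rng["baseline"].normal(0.0, cfg.baseline_log_sd, size=n_ogus)
    intercepts = rng["intercepts"].normal(
        0.0, cfg.dataset_intercept_sd, size=(cfg.n_datasets, n_ogus)
    )

    # allochthonous taxa: low-occupancy candidates, flagged oral/food, shifted NR-wards
    planted = effect_base.copy()
    n_flagged = int(round(cfg.frac_allochthonous * n_ogus))
    flags: list[list[str]] = [[] for _ in range(n_ogus)]
    if n_flagged > 0:
        order = np.argsort(occupancy, kind="stable")
        candidates = order[: max(n_flagged, n_ogus // 2)]
        chosen = rng["flags"].choice(candidates, size=n_flagged, replace=False)
        which = rng["flags"].random(n_flagged) < 0.5
        for idx, is_oral in zip(chosen, which):
            flags[idx] = ["oral" if is_oral else "food"]
        planted[chosen] -= cfg.allochthonous_nr_shift

    cutoff = cfg.marker_cutoff_multiple * cfg.effect_sd
    if cfg.effect_sd == 0:
        labels_truth = ["null"] * n_ogus
    else:
        labels_truth = [
            "R" if e >= cutoff else ("NR" if e <= -cutoff else "null") for e in planted
        ]

    # response labels: Bernoulli(response_balance), both levels forced per dataset
    responses = np.empty(n_total, dtype=object)
    dataset_of = np.empty(n_total, dtype=object)
    sample_ids: list[str] = []
    pos = 0
    for d, (size, _) in enumerate(zip(sizes, cancers)):
        draws = rng["labels"].random(size) < cfg.response_balance
        if draws.all():
            draws[rng["labels"].integers(size)] = False
        elif not draws.any():
            draws[rng["labels"].integers(size)] = True
        for k in range(size):
            sid = f"d{d:02d}_s{k:03d}"
            sample_ids.append(sid)
            responses[pos] = "R" if draws[k] else "NR"
            dataset_of[pos] = f"dataset_{d:02d}"
            pos += 1

    depths = np.maximum(
        np.round(rng["depths"].lognormal(cfg.depth_log_mean, cfg.depth_log_sd, n_total)),
        100,
    ).astype(np.int64)

    counts = np.zeros((n_total, n_ogus), dtype=np.int64)
    pos = 0
    for d, size in enumerate(sizes):
        noise = rng["noise"].normal(0.0, cfg.noise_log_sd, size=(size, n_ogus))
        masks = rng["occupancy_draws"].random((size, n_ogus)) < occupancy[None, :]
        for k in range(size):
            x = 1.0 if responses[pos] == "R" else 0.0
            logit = baseline + intercepts[d] + planted * x + noise[k]
            mask = masks[k]
            if not mask.any():  # degenerate draw: force the most prevalent taxon on
                mask[np.argmax(occupancy)] = True
            w = np.where(mask, np.exp(logit - logit.max()), 0.0)
            p = w / w.sum()
            counts[pos] = rng["occupancy_draws"].multinomial(depths[pos], p)
            pos += 1

    ogu_ids = [f"OGU{j:04d}" for j in range(n_ogus)]
    table = OguCountTable(sample_ids, ogu_ids, counts.astype(float))

    sample_meta = {
        sid: SampleMetadata(
            sample_id=sid,
            dataset_id=dataset_of[i],
            response=responses[i],
            cancer_type=cancers[int(dataset_of[i].split("_")[1])],
        )
        for i, sid in enumerate(sample_ids)
    }

    # gene families: designated GH subset enriched among true R markers
    gh = [f"GH{j}" for j in range(1, cfg.n_gene_families // 2 + 1)]
    ko = [f"K{j:05d}" for j in range(1, cfg.n_gene_families - len(gh) + 1)]
    families = gh + ko
    enriched = gh[: cfg.n_enriched_families]
    fam_rng = rng["families"]
    is_r_marker = np.array([lab == "R" for lab in labels_truth])
    gene_sets: list[frozenset[str]] = []
    for j in range(n_ogus):
        kept = []
        for fam in families:
            rate = (
                cfg.family_enriched_rate
                if (fam in enriched and is_r_marker[j])
                else cfg.family_base_rate
            )
            if fam_rng.random() < rate:
                kept.append(fam)
        gene_sets.append(frozenset(kept))

    qual = rng["quality"]
    phyla_names = [p for p, _ in _PHYLA]
    phyla_probs = np.array([w for _, w in _PHYLA])
    phyla_probs = phyla_probs / phyla_probs.sum()
    assigned_phyla = qual.choice(phyla_names, size=n_ogus, p=phyla_probs)
    completeness = np.clip(qual.normal(91.9, 6.8, n_ogus), 50.0, 100.0)
    contamination = np.clip(qual.normal(2.13, 2.77, n_ogus), 0.0, None)
    ogu_meta = {
        oid: OguMetadata(
            ogu_id=oid,
            taxonomy=(
                f"d__Bacteria;p__{assigned_phyla[j]};c__c{j % 7};o__o{j % 13};"
                f"f__f{j % 31};g__g{j};s__g{j} sp{j}"
            ),
            completeness=float(completeness[j]),
            contamination=float(contamination[j]),
            source_flags=frozenset(flags[j]),
            gene_families=gene_sets[j],
        )
        for j, oid in enumerate(ogu_ids)
    }

    truth = SimTruth(
        planted_effect=planted,
        effect_base=effect_base,
        true_marker_label=labels_truth,
        marker_cutoff=float(cutoff),
        dataset_intercepts=intercepts,
        occupancy=occupancy,
        source_flags=flags,
        enriched_families=list(enriched),
        depths=depths,
        seeds={"root": int(cfg.seed), **{s: i for i, s in enumerate(_STREAMS)}},
    )
    return table, sample_meta, ogu_meta, truth


def simulate_null(config: SimConfig, **overrides):
    """Cohorts with no planted signal: response labels carry no information.

    Forces ``effect_sd = 0`` and ``allochthonous_nr_shift = 0``; attempting
    to override either is an error.
    """
    forbidden = {"effect_sd", "allochthonous_nr_shift"} & overrides.keys()
    if forbidden:
        raise ValueError(f"simulate_null forbids overriding {sorted(forbidden)}")
    cfg = dataclasses.replace(
        config, effect_sd=0.0, allochthonous_nr_shift=0.0, **overrides
    )
    return simulate_cohorts(cfg)
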
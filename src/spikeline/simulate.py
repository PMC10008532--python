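"""Synthetic spiked-community experiments with known ground truth.

The generator emulates a spike-in study design: pooled sample communities
with log-normal rank-abundance, a defined mock community (MC) added at a
per-sample dose before DNA extraction, reduced extraction efficiency for
the gram-positive MC taxon, multinomial read sampling at fixed depth, and
low-frequency secondary MC sequence variants roughly 100× below the
primary variant of each taxon.

Copy pools are deterministic given the configuration; only read sampling
(and the community proportions) is stochastic, all driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import CountTable, MCReference, SVSequenceSet, ValidationError, validate_metadata
from .synthetic_references import default_references

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "SimulationError",
    "simulate_experiment",
    "inject_outlier",
    "study_design_config",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of one synthetic spike-in experiment.

    Per-sample sequences (``biomass_mass``, ``mc_dose_fraction``,
    ``outlier_fold``, ``pool_ids``, ``depth``) must all have length
    ``n_samples``; scalars are broadcast. ``copies_per_mg`` sets the true
    16S gene copies per mg of sample material; ``gram_pos_efficiency`` is
    the relative DNA-extraction efficiency of gram-positive taxa in (0, 1].
    ``secondary_sv_rate`` is the expected secondary:primary read ratio for
    each MC taxon (default 0.01, i.e. ~100× below the primary variant).
    """

    biomass_mass: Sequence[float]
    mc_dose_fraction: Sequence[float]
    n_taxa: int = 300
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    copies_per_mg: float = 4.3e7
    depth: int | Sequence[int] = 30_000
    gram_pos_efficiency: float = 0.336
    secondary_sv_rate: float = 0.01
    n_secondary_variants: int = 2
    outlier_fold: Sequence[float] | None = None
    pool_ids: Sequence[str] | None = None
    sample_ids: Sequence[str] | None = None
    references: list[MCReference] = field(default_factory=default_references)
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.biomass_mass)
        if len(self.mc_dose_fraction) != n:
            raise ValidationError("biomass_mass and mc_dose_fraction lengths differ")
        if np.isscalar(self.depth):
            self.depth = [int(self.depth)] * n
        if self.outlier_fold is None:
            self.outlier_fold = [1.0] * n
        if self.pool_ids is None:
            self.pool_ids = ["P1"] * n
        if self.sample_ids is None:
            self.sample_ids = [f"S{i + 1:03d}" for i in range(n)]
        if any(d < 1 for d in self.depth):
            raise ValidationError("depth must be >= 1")
        if not (0 < self.gram_pos_efficiency <= 1):
            raise ValidationError("gram_pos_efficiency must lie in (0, 1]")
        if any(f <= 0 for f in self.outlier_fold):
            raise ValidationError("outlier_fold must be > 0")
        if min(self.biomass_mass) < 0 or min(self.mc_dose_fraction) < 0:
            raise ValidationError("masses and doses must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.biomass_mass)

    def expected_gram_ratio(self) -> float:
        """Expected observed gram-negative : gram-positive read ratio.

        Extraction bias divides the gram-positive pool by
        ``gram_pos_efficiency``; the copy ratio itself is fixed by the dose.
        """
        neg = next(r for r in self.references if r.gram == "negative")
        pos = next(r for r in self.references if r.gram == "positive")
        return (neg.copies_per_dose / pos.copies_per_dose) / self.gram_pos_efficiency


@dataclass
class GroundTruth:
    """True copy pools behind a simulated experiment.

    ``per_sample`` columns: ``sample_id, pool_id, sample_copies`` (true
    sample 16S copies after any outlier fold), per-MC-taxon input and
    effective (post-bias) copies, ``expected_mc_fraction`` = effective MC /
    (effective MC + effective sample) in [0, 1], ``outlier_fold`` and
    ``is_outlier``.
    """

    per_sample: pd.DataFrame
    proportions: pd.DataFrame  # pools × taxa true relative abundances
    gram_pos_efficiency: float

    def expected_mc_fraction(self) -> pd.Series:
        return self.per_sample.set_index("sample_id")["expected_mc_fraction"]

    def total_effective_copies(self) -> pd.Series:
        df = self.per_sample.set_index("sample_id")
        return df["sample_copies"] + df["mc_effective_copies"]


@dataclass
class SimulatedExperiment:
    table: CountTable
    sequences: SVSequenceSet
    metadata: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def _mutate(sequence: str, k: int, rng: np.random.Generator) -> str:
    """Introduce k point mutations at distinct positions."""
    bases = "ACGT"
    seq = list(sequence)
    for pos in rng.choice(len(seq), size=k, replace=False):
        alternatives = [b for b in bases if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(0, 3)]
    return "".join(seq)


def _condition_labels(mass: float, dose: float) -> str:
    biomass = "HBM" if mass >= 10.0 else "LBM"
    if dose == 0:
        mc = "nMC"
    elif dose >= 0.1:
        mc = "HMC"
    else:
        mc = "LMC"
    return f"{biomass}-{mc}"


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Draw one complete experiment from the generator.

    Per sample: the sample copy pool ``biomass_mass × copies_per_mg ×
    outlier_fold`` is split across taxa by the pool's log-normal
    proportions; the MC pool is ``dose_fraction × copies_per_dose`` per
    taxon, with gram-positive pools multiplied by ``gram_pos_efficiency``;
    reads are drawn multinomially at the configured depth over all pools;
    each MC taxon's reads are then split between its primary variant and
    ``n_secondary_variants`` secondaries with expected secondary:primary
    ratio ``secondary_sv_rate``. Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    refs = config.references
    n_taxa = config.n_taxa

    # one community per pool, shared by its samples (technical replicates)
    pools = list(dict.fromkeys(config.pool_ids))
    proportions = {}
    for pool in pools:
        raw = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=n_taxa)
        proportions[pool] = raw / raw.sum()
    prop_df = pd.DataFrame(
        proportions, index=[f"SV_{i + 1:04d}" for i in range(n_taxa)]
    ).T

    # SV sequences: random fragments for sample taxa, reference-derived for MC
    seqs = {}
    for i in range(n_taxa):
        seqs[f"SV_{i + 1:04d}"] = "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, size=253)]
        )
    mc_sv_ids: dict[str, list[str]] = {}
    for ref in refs:
        tag = ref.name.split()[0][0] + ref.name.split()[-1][0]  # e.g. "Ih"
        primary = f"MC_{tag}_primary"
        seqs[primary] = ref.sequence
        ids = [primary]
        for v in range(config.n_secondary_variants):
            sid = f"MC_{tag}_sec{v + 1}"
            seqs[sid] = _mutate(ref.sequence, k=2, rng=rng)
            ids.append(sid)
        mc_sv_ids[ref.name] = ids

    sample_sv_ids = [f"SV_{i + 1:04d}" for i in range(n_taxa)]
    all_sv_ids = sample_sv_ids + [sid for ids in mc_sv_ids.values() for sid in ids]
    counts = np.zeros((config.n_samples, len(all_sv_ids)), dtype=np.int64)
    col_of = {sv: i for i, sv in enumerate(all_sv_ids)}

    truth_rows = []
    meta_rows = []
    for j in range(config.n_samples):
        mass = config.biomass_mass[j]
        dose = config.mc_dose_fraction[j]
        fold = config.outlier_fold[j]
        pool = config.pool_ids[j]
        depth = config.depth[j]
        sample_copies = mass * config.copies_per_mg * fold
        taxon_pool = sample_copies * prop_df.loc[pool].to_numpy()

        mc_input = {}
        mc_effective = {}
        for ref in refs:
            inp = dose * ref.copies_per_dose
            eff = inp * (config.gram_pos_efficiency if ref.gram == "positive" else 1.0)
            mc_input[ref.name] = inp
            mc_effective[ref.name] = eff

        pool_vec = np.concatenate([taxon_pool, [mc_effective[r.name] for r in refs]])
        total = pool_vec.sum()
        if total <= 0:
            raise SimulationError(f"sample {config.sample_ids[j]}: empty copy pool")
        reads = rng.multinomial(depth, pool_vec / total)

        counts[j, : n_taxa] = reads[:n_taxa]
        for k, ref in enumerate(refs):
            taxon_reads = reads[n_taxa + k]
            ids = mc_sv_ids[ref.name]
            r = config.secondary_sv_rate
            weights = np.array([1.0] + [r] * config.n_secondary_variants)
            split = rng.multinomial(taxon_reads, weights / weights.sum())
            for sid, nreads in zip(ids, split):
                counts[j, col_of[sid]] = nreads

        mc_eff_total = sum(mc_effective.values())
        row = {
            "sample_id": config.sample_ids[j],
            "pool_id": pool,
            "sample_copies": sample_copies,
            "mc_input_copies": sum(mc_input.values()),
            "mc_effective_copies": mc_eff_total,
            "expected_mc_fraction": mc_eff_total / (mc_eff_total + sample_copies),
            "outlier_fold": fold,
            "is_outlier": fold != 1.0,
        }
        for ref in refs:
            tag = ref.name.split()[0][0] + ref.name.split()[-1][0]
            row[f"{tag}_input_copies"] = mc_input[ref.name]
            row[f"{tag}_effective_copies"] = mc_effective[ref.name]
        truth_rows.append(row)
        meta_rows.append(
            {
                "sample_id": config.sample_ids[j],
                "pool_id": pool,
                "biomass_mass": mass,
                "mc_dose_fraction": dose,
                "replicate_label": f"r{j + 1}",
                "condition": _condition_labels(mass, dose),
            }
        )

    table = CountTable(pd.DataFrame(counts, index=config.sample_ids, columns=all_sv_ids))
    metadata = validate_metadata(pd.DataFrame(meta_rows))
    metadata["mc_biomass_ratio"] = np.where(
        metadata["biomass_mass"] > 0,
        metadata["mc_dose_fraction"] / metadata["biomass_mass"],
        np.nan,
    )
    truth = GroundTruth(
        per_sample=pd.DataFrame(truth_rows),
        proportions=prop_df,
        gram_pos_efficiency=config.gram_pos_efficiency,
    )
    return SimulatedExperiment(table, SVSequenceSet(seqs), metadata, truth, config)


def inject_outlier(config: SimulationConfig, sample_id: str, fold: float) -> SimulationConfig:
    """Return a config whose sample's true copy pool is multiplied by ``fold``.

    ``fold`` < 1 models under-extraction / low biomass (e.g. a replicate
    with 9.84× fewer copies than its group), ``fold`` > 1 the reverse.
    """
    if fold <= 0:
        raise ValidationError("fold must be > 0")
    if sample_id not in config.sample_ids:
        raise ValidationError(f"unknown sample_id {sample_id!r}")
    folds = list(config.outlier_fold)
    folds[list(config.sample_ids).index(sample_id)] *= fold
    return replace(config, outlier_fold=folds)


def study_design_config(
    seed: int = 0,
    n_pools: int = 3,
    replicates: int = 4,
    depth: int = 30_000,
    **overrides,
) -> SimulationConfig:
    """Config mirroring the two-mass × three-dose replicated pool design.

    Masses 50.0 mg (HBM) and 1.25 mg (LBM); MC dose fractions 0 (nMC),
    0.0125 (LMC) and 0.5 (HMC); ``replicates`` technical replicates per
    pool × condition.
    """
    masses, doses, pool_ids, sample_ids = [], [], [], []
    for p in range(1, n_pools + 1):
        for mass, mlab in ((50.0, "HBM"), (1.25, "LBM")):
            for dose, dlab in ((0.0, "nMC"), (0.0125, "LMC"), (0.5, "HMC")):
                for r in range(1, replicates + 1):
                    masses.append(mass)
                    doses.append(dose)
                    pool_ids.append(f"BP{p}")
                    sample_ids.append(f"BP{p}_{mlab}_{dlab}_r{r}")
    return SimulationConfig(
        biomass_mass=masses,
        mc_dose_fraction=doses,
        pool_ids=pool_ids,
        sample_ids=sample_ids,
        depth=depth,
        seed=seed,
        **overrides,
    )
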
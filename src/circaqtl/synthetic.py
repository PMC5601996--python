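"""Synthetic cohort generator for the circadian-QTL pipeline.

Emulates the statistical structure of a fibroblast circadian cohort:
diploid genotypes in Hardy-Weinberg equilibrium with block LD, cellular
circadian traits (clock-gene expression peaks, amplitude, phase, period)
with sparse additive SNP effects plus passage/date confounders and a
biological/technical replicate hierarchy, damped-oscillation
bioluminescence recordings, extreme-chronotype cohorts drawn from the
tails of a genetically driven behavioral score, genome-scale RNAi hairpin
screens, and 24 h-periodic timecourse matrices.

All generators are deterministic given ``SimulationConfig.seed``; each
stage draws from an independent substream derived from the global seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TRAITS = ("PER1", "PER2", "amplitude", "phase", "period")

#: per-trait (baseline, one trait-SD in native units).  Period is in hours
#: centred on 24.5 h; phase in hours after synchronization; amplitude and
#: the two clock-gene expression peaks are in arbitrary reporter units.
TRAIT_SCALES: Mapping[str, tuple[float, float]] = {
    "PER1": (100.0, 20.0),
    "PER2": (100.0, 20.0),
    "amplitude": (50.0, 10.0),
    "phase": (10.0, 1.5),
    "period": (24.5, 0.75),
}

_STAGE_OFFSETS = {
    "genotypes": 1,
    "phenotypes": 2,
    "traces": 3,
    "chronotype": 4,
    "rnai": 5,
    "timecourses": 6,
}


def _substream(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG substream for a pipeline stage, derived from the
    single global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_OFFSETS[stage]]))


@dataclass(frozen=True)
class ConfounderSpec:
    """Passage-number and experiment-date confounding.

    passage_beta: trait-units change per passage, per trait (scalar
    broadcasts to all traits); n_dates: number of experiment dates;
    date_sd: SD of the per-date random offset (trait-SD units).
    """

    passage_beta: Mapping[str, float] | float = 0.0
    n_dates: int = 4
    date_sd: float = 0.0

    def beta_for(self, trait: str) -> float:
        if isinstance(self.passage_beta, Mapping):
            return float(self.passage_beta.get(trait, 0.0))
        return float(self.passage_beta)


@dataclass(frozen=True)
class ReplicateSpec:
    n_biological: int = 3
    n_technical: int = 4
    bio_noise_sd: float = 1.0  # trait-SD units
    tech_noise_sd: float = 0.5


@dataclass(frozen=True)
class TraceSpec:
    sampling_interval_h: float = 0.5
    duration_h: float = 120.0
    noise_sd: float = 2.0
    damping_rate: float = 0.02  # per hour
    baseline_mu: float = 200.0  # initial non-oscillatory photon count
    baseline_tau_h: float = 48.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    causal_spec entries are (snp_index, trait_name, effect_size) with the
    effect in trait-SD units per copy of the ALT allele.
    """

    n_samples: int = 159
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_flip_rate: float = 0.05
    missing_rate: float = 0.0
    causal_spec: Sequence[tuple[int, str, float]] = ()
    confounder_spec: ConfounderSpec = field(default_factory=ConfounderSpec)
    replicate_spec: ReplicateSpec = field(default_factory=ReplicateSpec)
    trace_spec: TraceSpec = field(default_factory=TraceSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(
                f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range!r}"
            )
        for name in ("n_samples", "n_snps", "ld_block_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for idx, trait, beta in self.causal_spec:
            if trait not in TRAITS:
                raise ValueError(f"unknown trait {trait!r} in causal_spec")
            if not np.isfinite(beta):
                raise ValueError("effect sizes must be finite")
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"causal snp index {idx} out of range [0, {self.n_snps})")


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid dosage table with variant metadata.

    ``dosages`` is float with values in {0, 1, 2} and NaN for missing.
    ``variants`` carries chrom, pos (1-based), snp_id, ref, alt, info_score.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in keep]
        return GenotypeMatrix(list(keep), self.variants.copy(), self.dosages[rows])

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            self.variants.loc[mask].reset_index(drop=True),
            self.dosages[:, np.asarray(mask)],
        )

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.samples, columns=self.variants["snp_id"].tolist()
        )


@dataclass
class CohortTruth:
    """Ground truth for recovery tests: which SNPs drive which trait, the
    per-sample latent trait values, and the per-SNP weights that define
    the behavioral chronotype score."""

    causal_indices: Mapping[str, list[int]]
    latent: pd.DataFrame  # index sample id, columns TRAITS
    chronotype_weights: Mapping[int, float]
    chronotype_score: pd.Series | None = None


@dataclass
class ChronotypeCohort:
    larks: GenotypeMatrix
    owls: GenotypeMatrix

    def __post_init__(self) -> None:
        if set(self.larks.samples) & set(self.owls.samples):
            raise ValueError("lark and owl sample sets must be disjoint")
        if list(self.larks.variants["snp_id"]) != list(self.owls.variants["snp_id"]):
            raise ValueError("cohorts must share the same variant panel")


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate diploid dosages in HWE with block LD.

    Haplotypes are drawn per LD block: a block-ancestor allele with
    frequency drawn from ``maf_range``, copied to each SNP of the block
    with a per-SNP recombination-like flip probability.  Genotype =
    haplotype sum, so HWE holds exactly.
    """
    rng = _substream(config.seed, "genotypes")
    n, m = config.n_samples, config.n_snps
    samples = [f"S{i:04d}" for i in range(n)]
    block = max(config.ld_block_size, 1)
    n_blocks = -(-m // block) if m else 0

    dosages = np.empty((n, m), dtype=float)
    freqs = np.empty(m)
    for b in range(n_blocks):
        lo, hi = b * block, min((b + 1) * block, m)
        f_anc = rng.uniform(*config.maf_range)
        # two ancestor haplotypes per sample
        anc = rng.random((n, 2)) < f_anc
        for j in range(lo, hi):
            flips = rng.random((n, 2)) < config.ld_flip_rate
            hap = anc ^ flips
            dosages[:, j] = hap.sum(axis=1)
            freqs[j] = f_anc * (1 - config.ld_flip_rate) + (1 - f_anc) * config.ld_flip_rate
    if config.missing_rate > 0 and m:
        miss = rng.random((n, m)) < config.missing_rate
        dosages[miss] = np.nan

    variants = pd.DataFrame(
        {
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 1000,
            "snp_id": [f"rs{j + 1:06d}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "info_score": np.ones(m),
            "target_freq": freqs,
        }
    )
    return GenotypeMatrix(samples, variants, dosages)


def _passage_and_dates(
    rng: np.random.Generator, n_lines: int, n_bio: int, n_dates: int
) -> tuple[np.ndarray, np.ndarray]:
    passages = rng.integers(3, 13, size=(n_lines, n_bio))
    dates = rng.integers(0, max(n_dates, 1), size=(n_lines, n_bio))
    return passages, dates


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, CohortTruth]:
    """Replicated trait table plus ground truth.

    Per replicate row: value = baseline + sd * (sum beta*dosage
    + passage_beta*passage + date offset + biological noise + technical
    noise), i.e. genetic and confounder effects act in trait-SD units and
    are mapped to native units through the per-trait scale.
    """
    for idx, trait, _ in config.causal_spec:
        if idx >= genotypes.n_snps:
            raise ValueError(f"causal snp index {idx} out of range for genotype matrix")
    rng = _substream(config.seed, "phenotypes")
    rep = config.replicate_spec
    conf = config.confounder_spec
    n = genotypes.n_samples
    dos = np.nan_to_num(genotypes.dosages, nan=0.0)

    causal: dict[str, list[int]] = {t: [] for t in TRAITS}
    genetic = {t: np.zeros(n) for t in TRAITS}
    weights: dict[int, float] = {}
    for idx, trait, beta in config.causal_spec:
        genetic[trait] += beta * dos[:, idx]
        causal[trait].append(idx)
        weights[idx] = weights.get(idx, 0.0) + beta

    date_offsets = {t: rng.normal(0.0, conf.date_sd, size=max(conf.n_dates, 1)) for t in TRAITS}
    passages, dates = _passage_and_dates(rng, n, rep.n_biological, conf.n_dates)

    latent = pd.DataFrame(index=pd.Index(genotypes.samples, name="line_id"))
    rows: dict[str, list] = {k: [] for k in (
        "line_id", "biological_replicate", "technical_replicate",
        "trait", "value", "passage", "date")}
    for trait in TRAITS:
        base, sd = TRAIT_SCALES[trait]
        beta_p = conf.beta_for(trait)
        latent[trait] = base + sd * genetic[trait]
        bio_noise = rng.normal(0.0, rep.bio_noise_sd, size=(n, rep.n_biological))
        tech_noise = rng.normal(
            0.0, rep.tech_noise_sd, size=(n, rep.n_biological, rep.n_technical)
        )
        for b in range(rep.n_biological):
            for t in range(rep.n_technical):
                z = (
                    genetic[trait]
                    + beta_p * passages[:, b]
                    + date_offsets[trait][dates[:, b]]
                    + bio_noise[:, b]
                    + tech_noise[:, b, t]
                )
                rows["line_id"].extend(genotypes.samples)
                rows["biological_replicate"].extend([b + 1] * n)
                rows["technical_replicate"].extend([t + 1] * n)
                rows["trait"].extend([trait] * n)
                rows["value"].extend(base + sd * z)
                rows["passage"].extend(passages[:, b])
                rows["date"].extend(f"d{d + 1}" for d in dates[:, b])

    table = pd.DataFrame(rows)
    truth = CohortTruth(causal_indices=causal, latent=latent, chronotype_weights=weights)
    return table, truth


@dataclass
class BioluminescenceTrace:
    """One photon-count recording after dexamethasone synchronization."""

    line_id: str
    replicate_id: str
    time_h: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_h.ndim != 1 or self.time_h.shape != self.signal.shape:
            raise ValueError("time_h and signal must be matching 1-D arrays")
        if len(self.time_h) > 1 and not np.all(np.diff(self.time_h) > 0):
            raise ValueError("time_h must be strictly increasing")

    @property
    def span_h(self) -> float:
        return float(self.time_h[-1] - self.time_h[0])


def damped_oscillation(
    t: np.ndarray,
    period_h: float,
    phase_h: float,
    amplitude: float,
    damping_rate: float = 0.0,
    baseline_mu: float = 0.0,
    baseline_tau_h: float = np.inf,
) -> np.ndarray:
    """y(t) = mu_b exp(-t/tau_b) + A exp(-lambda t) cos(2 pi (t-phi)/T)."""
    t = np.asarray(t, dtype=float)
    if period_h <= 0:
        raise ValueError("period must be positive")
    base = baseline_mu * np.exp(-t / baseline_tau_h) if baseline_mu else np.zeros_like(t)
    osc = amplitude * np.exp(-damping_rate * t) * np.cos(2 * np.pi * (t - phase_h) / period_h)
    return base + osc


def simulate_traces(
    phenotypes: pd.DataFrame, config: SimulationConfig
) -> list[BioluminescenceTrace]:
    """One damped-cosine trace per (line, biological, technical) replicate,
    using that replicate's period/phase/amplitude phenotype values."""
    rng = _substream(config.seed, "traces")
    spec = config.trace_spec
    t = np.arange(0.0, spec.duration_h + 1e-9, spec.sampling_interval_h)
    wide = phenotypes.pivot_table(
        index=["line_id", "biological_replicate", "technical_replicate"],
        columns="trait",
        values="value",
    )
    missing = {"period", "phase", "amplitude"} - set(wide.columns)
    if missing:
        raise ValueError(f"phenotype table lacks trace traits: {sorted(missing)}")
    traces = []
    for (line, bio, tech), row in wide.iterrows():
        if row["period"] <= 0:
            raise ValueError(f"non-positive period for line {line}")
        y = damped_oscillation(
            t,
            period_h=row["period"],
            phase_h=row["phase"],
            amplitude=max(row["amplitude"], 0.0),
            damping_rate=spec.damping_rate,
            baseline_mu=spec.baseline_mu,
            baseline_tau_h=spec.baseline_tau_h,
        )
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=t.shape)
        traces.append(BioluminescenceTrace(line, f"b{bio}t{tech}", t.copy(), y))
    return traces


def simulate_chronotype_cohorts(
    genotypes: GenotypeMatrix,
    truth: CohortTruth,
    n_larks: int,
    n_owls: int,
    seed: int,
    noise_sd: float = 1.0,
) -> ChronotypeCohort:
    """Extreme-chronotype cohorts from a behavioral population.

    ``genotypes`` should be a freshly simulated population on the same
    variant panel as the GWAS cohort.  Score = sum of chronotype weights
    times causal dosages + N(0, noise_sd); larks are the lowest-score
    extremes ("early"), owls the highest.
    """
    if n_larks < 1 or n_owls < 1:
        raise ValueError("n_larks and n_owls must each be >= 1")
    if n_larks + n_owls > genotypes.n_samples:
        raise ValueError(
            f"requested {n_larks + n_owls} extremes from a population of {genotypes.n_samples}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_OFFSETS["chronotype"]]))
    dos = np.nan_to_num(genotypes.dosages, nan=0.0)
    score = np.zeros(genotypes.n_samples)
    for idx, w in truth.chronotype_weights.items():
        score += w * dos[:, idx]
    score = score + rng.normal(0.0, noise_sd, size=score.shape)
    order = np.argsort(score, kind="stable")
    lark_ids = [genotypes.samples[i] for i in order[:n_larks]]
    owl_ids = [genotypes.samples[i] for i in order[-n_owls:]]
    truth.chronotype_score = pd.Series(score, index=genotypes.samples, name="chronotype")
    return ChronotypeCohort(
        larks=genotypes.subset_samples(lark_ids), owls=genotypes.subset_samples(owl_ids)
    )


def simulate_rnai_screen(
    genelist: Sequence[str],
    genome_size: int,
    hairpins_per_gene: int,
    effect_spec: Mapping[str, float] | None,
    seed: int,
    hairpin_noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Genome-scale hairpin screen: background hairpins ~ N(0,1) per trait;
    genelist genes get a shared per-gene shift from ``effect_spec``
    (trait -> shift in screen SD units) plus per-hairpin noise.

    Returns long table (hairpin_id, gene_id, trait, value).
    """
    if hairpins_per_gene < 1:
        raise ValueError("hairpins_per_gene must be >= 1")
    genelist = list(genelist)
    if genome_size < len(set(genelist)):
        raise ValueError("genome_size smaller than the gene list")
    effect_spec = dict(effect_spec or {})
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_OFFSETS["rnai"]]))
    genes = [f"GENE{g:05d}" for g in range(genome_size)]
    # map genelist names onto the first len(genelist) genome slots unless
    # the caller already used genome ids
    alias = {}
    for k, name in enumerate(genelist):
        alias[name] = name if name in genes else genes[k]
    traits = ("period", "amplitude")
    n_hp = genome_size * hairpins_per_gene
    listed = {alias[g] for g in genelist}
    gene_col = np.repeat(genes, hairpins_per_gene)
    hp_col = np.array(
        [f"{g}_hp{h + 1}" for g in genes for h in range(hairpins_per_gene)]
    )
    in_list = np.isin(gene_col, sorted(listed))
    frames = []
    for trait in traits:
        values = rng.normal(0.0, 1.0, size=n_hp)
        shift = effect_spec.get(trait, 0.0)
        if shift:
            gene_effects = np.repeat(
                rng.normal(shift, hairpin_noise_sd, size=genome_size), hairpins_per_gene
            )
            values = np.where(in_list, values + gene_effects, values)
        frames.append(pd.DataFrame({
            "hairpin_id": hp_col, "gene_id": gene_col, "trait": trait, "value": values,
        }))
    table = pd.concat(frames, ignore_index=True)
    table.attrs["genelist"] = sorted(listed)
    return table


def simulate_timecourses(
    n_series: int,
    frac_rhythmic: float,
    times: Sequence[float],
    amp_range: tuple[float, float] = (1.0, 2.0),
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """24 h-periodic timecourse matrix with truth labels.

    Rhythmic rows follow mu + a sin(2 pi t/24) + b cos(2 pi t/24) + noise
    with amplitude sqrt(a^2+b^2) drawn from amp_range and random acrophase;
    the rest are flat + noise.  Returns (wide matrix indexed by series id
    with one column per timepoint, boolean rhythmic labels).
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0:
        raise ValueError("time grid must be non-empty")
    if not 0.0 <= frac_rhythmic <= 1.0:
        raise ValueError("frac_rhythmic must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_OFFSETS["timecourses"]]))
    n_rhythmic = int(round(frac_rhythmic * n_series))
    labels = np.zeros(n_series, dtype=bool)
    labels[:n_rhythmic] = True
    data = np.empty((n_series, times.size))
    for i in range(n_series):
        mu = rng.normal(0.0, 1.0)
        if labels[i]:
            amp = rng.uniform(*amp_range)
            theta = rng.uniform(0.0, 2 * np.pi)
            a, b = amp * np.sin(theta), amp * np.cos(theta)
            y = mu + a * np.sin(2 * np.pi * times / 24.0) + b * np.cos(2 * np.pi * times / 24.0)
        else:
            y = np.full(times.size, mu)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=times.size)
        data[i] = y
    matrix = pd.DataFrame(
        data, index=[f"series{i:04d}" for i in range(n_series)], columns=times
    )
    matrix.columns.name = "time_h"
    return matrix, labels


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)
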
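"""Synthetic mesocosm experiments with a known compositional threshold.

The generator emulates the statistical structure of a pond-mesocosm
disturbance experiment: 30 mesocosms (15 burned / 15 unburned) receive plant
material along a 0-400 g loading gradient and are sampled on several days.
Free-living water communities are modelled as a two-state mixture: below a
true loading threshold samples draw from a "low-loading" composition, above
it from a "high-loading" composition, with a logistic mixing weight

    w(loading) = 1 / (1 + exp(-sharpness * (loading - true_threshold_g)))

Per-sample taxon proportions are Dirichlet-distributed around the mixture
mean (compositional overdispersion) and read counts are multinomial at a
negative-binomially drawn sequencing depth. Environmental variables follow
hinge (piecewise-linear) functions of loading whose below/above slopes
converge on later sampling days, so the loading->environment relationship is
genuinely piecewise early and near-linear late. Host- and detritus-associated
microbiomes are convex mixtures of a source-specific composition and the
water composition ("environmental filtering" with a tunable water affinity).

Everything downstream needs ground truth; :func:`generate_experiment` returns
it alongside the tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .config import ConfigError, _from_mapping
from .tables import ENV_VARIABLES, CountTable

#: Per-variable hinge parameters (intercept, slope below the breakpoint,
#: slope above it, Gaussian noise SD) at the first sampling day. Units are
#: the variables' natural ones (% saturation, mg C/L, dimensionless optical
#: indices, pH units, deg C); slopes are per gram of plant material. Signs
#: follow browning chemistry: oxygen and humification-at-source drop steeply
#: over 0-100 g then flatten, DOC/aromaticity/freshness rise, temperature is
#: loading-independent.
DEFAULT_ENV_PROFILES: dict[str, tuple[float, float, float, float]] = {
    "percent_DO": (95.0, -0.55, -0.010, 4.0),
    "DOC": (5.0, 0.35, 0.080, 2.0),
    "FI": (1.40, -0.0008, -0.0004, 0.05),
    "BIX": (0.50, 0.0020, 0.0004, 0.04),
    "HIX": (0.85, -0.0030, -0.0004, 0.05),
    "Sr": (0.80, 0.0015, 0.0004, 0.05),
    "SUVA254": (2.00, 0.020, 0.0050, 0.15),
    "pH": (8.20, -0.0080, -0.0010, 0.12),
    "temperature": (15.0, 0.0, 0.0, 0.8),
}

#: Convex-mixture weight toward the water community per non-water source.
#: Daphnia filter-feed on the water column (high affinity); mosquito larvae
#: and decomposing plant material carry more source-specific communities.
DEFAULT_HOST_WATER_AFFINITY: dict[str, float] = {
    "daphnia": 0.7,
    "mosquito": 0.3,
    "sage": 0.15,
    "willow": 0.15,
}


@dataclass
class SyntheticExperimentConfig:
    """Full parameterization of a simulated mesocosm experiment."""

    n_mesocosms: int = 30
    n_per_treatment: int = 15
    n_controls: int = 0  # extra unloaded mesocosms coded treatment='control'
    loading_grid: Sequence[float] | None = None  # default: linspace(0,400,15)
    days: Sequence[int] = (10, 59, 89)
    n_taxa: int = 150
    depth_mean: float = 15000.0
    depth_dispersion: float = 20.0  # NB shape; larger = tighter depths
    true_threshold_g: float = 100.0
    state_mixing_sharpness: float = 0.1  # logistic steepness per gram
    effect_size: float = 1.0  # 0 = states identical
    state_alpha: float = 0.5  # Dirichlet concentration of the state draws
    burning_effect_size: float = 0.15
    burning_taxon_fraction: float = 0.2
    temporal_drift_size: float = 0.5
    dirichlet_concentration: float = 150.0  # per-sample compositional noise
    env_breakpoint_g: float = 100.0
    env_profiles: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENV_PROFILES))
    env_attenuation_rate: float = 0.03  # per day; hinge decay after day 1
    env_noise_scale: float = 1.0
    genome_size_range: tuple[float, float] = (2.0e6, 8.0e6)
    cds_per_bp: float = 9.0e-4
    doubling_time_range: tuple[float, float] = (1.0, 40.0)
    trait_state_bias: bool = True
    genome_size_bias: float = 8.0e5  # bp removed per SD of state-2 enrichment
    growth_bias: float = 0.3  # log-fold doubling-time reduction per SD
    plasticity_scale: float = 0.05
    plasticity_state_bias: float = 0.5
    plasticity_noise_sd: float = 0.01
    n_pathways: int = 40
    pathway_prevalence: float = 0.05  # sparse, MetaCyc-like incidence
    pathway_niche_strength: float = 6.0  # how strongly pathways track states
    include_hosts: bool = True
    host_water_affinity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HOST_WATER_AFFINITY))
    host_affinity_loading_slope: float = 0.0  # affinity change per gram
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ConfigError("n_taxa must be >= 2")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be > 0")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.loading_grid is None:
            self.loading_grid = tuple(
                np.round(np.linspace(0.0, 400.0, self.n_per_treatment), 4))
        grid = np.asarray(self.loading_grid, dtype=float)
        if grid.min() < 0 or grid.max() > 400:
            raise ConfigError("loading_grid values must lie in [0, 400]")
        if not (grid.min() < self.true_threshold_g < grid.max()):
            raise ConfigError(
                "true_threshold_g must lie strictly inside the loading range")
        if self.n_mesocosms != 2 * self.n_per_treatment:
            raise ConfigError(
                "n_mesocosms must equal 2 * n_per_treatment (plus n_controls "
                "extra control mesocosms)")
        extra = set(self.env_profiles) - set(ENV_VARIABLES)
        missing = set(ENV_VARIABLES) - set(self.env_profiles)
        if extra or missing:
            raise ConfigError(
                f"env_profiles must cover exactly {list(ENV_VARIABLES)}; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}")


def load_experiment_config(path) -> SyntheticExperimentConfig:
    import yaml
    from pathlib import Path
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return _from_mapping(SyntheticExperimentConfig, data, str(path))


@dataclass
class SyntheticExperiment:
    """Everything one simulated run produces, plus ground truth."""

    counts_by_day: dict[int, CountTable]
    metadata: pd.DataFrame
    environment: pd.DataFrame
    traits: pd.DataFrame
    gene_dissimilarity: pd.DataFrame
    proteome_dissimilarity: pd.DataFrame
    pathway_incidence: pd.DataFrame
    ground_truth: dict

    def water_table(self, day: int) -> CountTable:
        """Free-living water samples for one day."""
        ids = self.metadata.index[(self.metadata["day"] == day)
                                  & (self.metadata["source"] == "water")]
        return self.counts_by_day[day].select_samples(ids)


def mixing_weight(loading_g, sharpness: float, threshold_g: float):
    """Logistic weight of the high-loading state at a given loading."""
    return 1.0 / (1.0 + np.exp(-sharpness * (np.asarray(loading_g, float)
                                             - threshold_g)))


def _softmax_log(logp: np.ndarray) -> np.ndarray:
    logp = logp - logp.max()
    p = np.exp(logp)
    return p / p.sum()


def generate_environment(loading_g: float, day: int,
                         config: SyntheticExperimentConfig,
                         rng: np.random.Generator) -> dict[str, float]:
    """One environment row: hinge in loading, slopes attenuating with day."""
    lo, hi = (min(config.days), None)
    g = float(np.exp(-config.env_attenuation_rate * (day - lo)))
    bp = config.env_breakpoint_g
    row = {}
    for var in ENV_VARIABLES:
        b0, s_below, s_above, sd = config.env_profiles[var]
        mean_slope = 0.5 * (s_below + s_above)
        sb = mean_slope + (s_below - mean_slope) * g
        sa = mean_slope + (s_above - mean_slope) * g
        value = (b0 + sb * min(loading_g, bp)
                 + sa * max(loading_g - bp, 0.0))
        if config.env_noise_scale > 0 and sd > 0:
            value += rng.normal(0.0, sd * config.env_noise_scale)
        row[var] = value
    return row


def generate_traits(n_taxa: int, config: SyntheticExperimentConfig,
                    rng: np.random.Generator,
                    state_enrichment: np.ndarray | None = None):
    """Per-taxon genome traits plus gene/proteome dissimilarity matrices.

    When ``config.trait_state_bias`` is set and a state-enrichment vector is
    supplied, taxa enriched in the high-loading state get smaller genomes,
    shorter doubling times and higher genomic plasticity (streamlining under
    stress).
    """
    if n_taxa < 2:
        raise ConfigError("n_taxa must be >= 2")
    taxa = [f"t{i:04d}" for i in range(n_taxa)]
    if state_enrichment is None or not config.trait_state_bias:
        z = np.zeros(n_taxa)
    else:
        e = np.asarray(state_enrichment, dtype=float)
        z = (e - e.mean()) / (e.std() if e.std() > 0 else 1.0)

    lo, hi = config.genome_size_range
    genome = rng.uniform(lo, hi, n_taxa) - config.genome_size_bias * z
    genome = np.clip(genome, 0.5e6, None)
    cds = np.round(genome * config.cds_per_bp
                   * np.exp(rng.normal(0.0, 0.05, n_taxa))).astype(int)
    dlo, dhi = config.doubling_time_range
    doubling = np.exp(rng.uniform(np.log(dlo), np.log(dhi), n_taxa)
                      - config.growth_bias * z)
    traits = pd.DataFrame({
        "genome_size_bp": genome,
        "n_coding_sequences": cds,
        "doubling_time_h": doubling,
    }, index=pd.Index(taxa, name="taxon_id"))

    # Marker-gene space: latent planar coordinates; proteome space adds a
    # per-taxon divergence offset (the ground-truth plasticity signal).
    coords = rng.uniform(0.0, 1.0, (n_taxa, 2))
    d_gene = squareform(pdist(coords))
    d_gene /= max(d_gene.max(), 1e-12) * 1.25  # keep headroom below 1
    eps = config.plasticity_scale * (np.abs(rng.normal(0.0, 1.0, n_taxa))
                                     + config.plasticity_state_bias
                                     * np.clip(z, 0.0, None))
    noise = rng.normal(0.0, config.plasticity_noise_sd, (n_taxa, n_taxa))
    noise = 0.5 * (noise + noise.T)
    d_prot = d_gene + 0.5 * (eps[:, None] + eps[None, :]) + noise
    np.fill_diagonal(d_prot, 0.0)
    d_prot = np.clip(0.5 * (d_prot + d_prot.T), 0.0, 1.0)
    idx = pd.Index(taxa, name="taxon_id")
    return (traits,
            pd.DataFrame(d_gene, index=idx, columns=taxa),
            pd.DataFrame(d_prot, index=idx, columns=taxa),
            eps)


def _draw_depth(rng: np.random.Generator,
                config: SyntheticExperimentConfig) -> int:
    shape = config.depth_dispersion
    p = shape / (shape + config.depth_mean)
    return int(max(1, rng.negative_binomial(shape, p)))


def generate_experiment(config: SyntheticExperimentConfig | None = None
                        ) -> SyntheticExperiment:
    """Simulate a complete mesocosm experiment under ``config``."""
    if config is None:
        config = SyntheticExperimentConfig()
    rng = np.random.default_rng(config.rng_seed)
    n_taxa = config.n_taxa
    taxa = [f"t{i:04d}" for i in range(n_taxa)]

    # --- mesocosm design -------------------------------------------------
    grid = np.asarray(config.loading_grid, dtype=float)
    rows = []
    mid = 0
    for treatment in ("burned", "unburned"):
        for loading in grid:
            rows.append((f"m{mid:02d}", float(loading), treatment))
            mid += 1
    for _ in range(config.n_controls):
        rows.append((f"m{mid:02d}", 0.0, "control"))
        mid += 1
    design = pd.DataFrame(rows, columns=["mesocosm_id", "loading_g",
                                         "treatment"])

    # --- latent community states ----------------------------------------
    state1 = rng.dirichlet(np.full(n_taxa, config.state_alpha))
    state2_raw = rng.dirichlet(np.full(n_taxa, config.state_alpha))
    lam = 1.0 - np.exp(-config.effect_size)  # 0 -> identical states
    floor = 1e-12
    log1, log2r = np.log(state1 + floor), np.log(state2_raw + floor)
    state2 = _softmax_log((1.0 - lam) * log1 + lam * log2r)
    if config.effect_size == 0.0:
        state2 = state1.copy()
    enrichment = np.log(state2 + floor) - np.log(state1 + floor)

    n_burn = int(round(config.burning_taxon_fraction * n_taxa))
    burn_idx = rng.choice(n_taxa, size=n_burn, replace=False)
    burn_tilt = np.zeros(n_taxa)
    burn_tilt[burn_idx] = rng.normal(0.0, 1.0, n_burn) \
        * config.burning_effect_size
    day_tilt = {d: rng.normal(0.0, 1.0, n_taxa) * config.temporal_drift_size
                for d in config.days}

    source_base = {s: rng.dirichlet(np.full(n_taxa, config.state_alpha))
                   for s in config.host_water_affinity}

    # --- samples ---------------------------------------------------------
    meta_rows, env_rows = [], []
    counts_by_day: dict[int, list] = {d: [] for d in config.days}
    sample_w: dict[str, float] = {}
    final_day = max(config.days)
    load_mid = 0.5 * (grid.min() + grid.max())

    for _, m in design.iterrows():
        w = float(mixing_weight(m.loading_g, config.state_mixing_sharpness,
                                config.true_threshold_g))
        for d in config.days:
            mix = (1.0 - w) * state1 + w * state2
            logm = np.log(mix + floor) + day_tilt[d]
            if m.treatment == "burned":
                logm = logm + burn_tilt
            mean_props = _softmax_log(logm)
            sid = f"{m.mesocosm_id}_d{d:03d}_water"
            p = rng.dirichlet(config.dirichlet_concentration * mean_props
                              + 1e-9)
            counts = rng.multinomial(_draw_depth(rng, config), p)
            counts_by_day[d].append((sid, counts))
            meta_rows.append((sid, m.mesocosm_id, m.loading_g, m.treatment,
                              d, "water"))
            env_rows.append((sid, generate_environment(m.loading_g, d,
                                                       config, rng)))
            sample_w[sid] = w
            if d == final_day and config.include_hosts:
                for src, aff in config.host_water_affinity.items():
                    a = float(np.clip(
                        aff + config.host_affinity_loading_slope
                        * (m.loading_g - load_mid), 0.0, 1.0))
                    hmix = a * mean_props + (1.0 - a) * source_base[src]
                    hsid = f"{m.mesocosm_id}_d{d:03d}_{src}"
                    hp = rng.dirichlet(
                        config.dirichlet_concentration * hmix + 1e-9)
                    hcounts = rng.multinomial(_draw_depth(rng, config), hp)
                    counts_by_day[d].append((hsid, hcounts))
                    meta_rows.append((hsid, m.mesocosm_id, m.loading_g,
                                      m.treatment, d, src))
                    sample_w[hsid] = w

    tables = {}
    for d in config.days:
        ids = [sid for sid, _ in counts_by_day[d]]
        mat = np.vstack([c for _, c in counts_by_day[d]])
        tables[d] = CountTable(pd.DataFrame(mat, index=ids, columns=taxa))

    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "mesocosm_id", "loading_g",
                            "treatment", "day", "source"]
    ).set_index("sample_id")
    environment = pd.DataFrame(
        [r for _, r in env_rows],
        index=pd.Index([s for s, _ in env_rows], name="sample_id"),
    )[list(ENV_VARIABLES)]

    traits, d_gene, d_prot, eps = generate_traits(
        n_taxa, config, rng, state_enrichment=enrichment)

    # Pathways track clades: membership probability is tilted by each
    # taxon's state affinity, so some pathways concentrate in taxa favoured
    # at high (or low) loading and respond strongly to the gradient.
    ez = (enrichment - enrichment.mean())
    ez = ez / (ez.std() if ez.std() > 0 else 1.0)
    niche = rng.normal(0.0, config.pathway_niche_strength, config.n_pathways)
    base_logit = np.log(config.pathway_prevalence
                        / (1.0 - config.pathway_prevalence))
    p_member = 1.0 / (1.0 + np.exp(-(base_logit + niche[:, None]
                                     * ez[None, :])))
    inc = rng.random((config.n_pathways, n_taxa)) < p_member
    for k in np.flatnonzero(~inc.any(axis=1)):
        inc[k, rng.integers(n_taxa)] = True
    pathways = pd.DataFrame(
        inc.astype(int),
        index=pd.Index([f"pwy{k:03d}" for k in range(config.n_pathways)],
                       name="pathway_id"),
        columns=taxa)

    ground_truth = {
        "state1": state1.tolist(),
        "state2": state2.tolist(),
        "taxon_log_enrichment": enrichment.tolist(),
        "mixing_weight": sample_w,
        "true_threshold_g": config.true_threshold_g,
        "env_breakpoint_g": config.env_breakpoint_g,
        "plasticity_offsets": eps.tolist(),
        "burn_tilt": burn_tilt.tolist(),
        "config": dataclasses.asdict(config),
    }
    return SyntheticExperiment(tables, metadata, environment, traits,
                               d_gene, d_prot, pathways, ground_truth)


def save_experiment(exp: SyntheticExperiment, out_dir) -> None:
    """Write every table of an experiment into a directory (TSV/CSV/JSON)."""
    from pathlib import Path

    from .tables import (write_count_table, write_environment,
                         write_json, write_metadata)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for day, table in exp.counts_by_day.items():
        write_count_table(table, out / f"counts_day{day:03d}.tsv")
    write_metadata(exp.metadata, out / "metadata.csv")
    write_environment(exp.environment, out / "environment.csv")
    exp.traits.to_csv(out / "traits.tsv", sep="\t")
    exp.gene_dissimilarity.to_csv(out / "gene_dissimilarity.tsv", sep="\t")
    exp.proteome_dissimilarity.to_csv(out / "proteome_dissimilarity.tsv",
                                      sep="\t")
    exp.pathway_incidence.to_csv(out / "pathway_incidence.tsv", sep="\t")
    write_json(exp.ground_truth, out / "ground_truth.json")


def load_experiment(in_dir) -> SyntheticExperiment:
    """Read an experiment directory written by :func:`save_experiment`."""
    import json as _json
    import re
    from pathlib import Path

    from .tables import read_count_table, read_environment, read_metadata
    src = Path(in_dir)
    counts = {}
    for path in sorted(src.glob("counts_day*.tsv")):
        day = int(re.search(r"counts_day(\d+)", path.name).group(1))
        counts[day] = read_count_table(path)
    if not counts:
        raise FileNotFoundError(f"no counts_day*.tsv files in {src}")
    metadata = read_metadata(src / "metadata.csv")
    environment = read_environment(src / "environment.csv")
    traits = pd.read_csv(src / "traits.tsv", sep="\t", index_col=0)
    d_gene = pd.read_csv(src / "gene_dissimilarity.tsv", sep="\t",
                         index_col=0)
    d_prot = pd.read_csv(src / "proteome_dissimilarity.tsv", sep="\t",
                         index_col=0)
    pathways = pd.read_csv(src / "pathway_incidence.tsv", sep="\t",
                           index_col=0)
    gt_path = src / "ground_truth.json"
    ground_truth = (_json.loads(gt_path.read_text()) if gt_path.exists()
                    else {})
    return SyntheticExperiment(counts, metadata, environment, traits,
                               d_gene, d_prot, pathways, ground_truth)
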
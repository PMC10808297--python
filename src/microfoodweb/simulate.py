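"""Synthetic soil-community generator with plantable structure.

Emulates the statistical shape of a phosphorus-gradient field trial:
4 treatments × 3 replicates by default, genus-level count tables for three
kingdoms, nematode guild composition shifting along the treatment schedule,
overdispersed (negative-binomial) counts, and *latent factors* that plant
monotone cross-taxon associations strong enough for the co-occurrence
module to recover.

The count model is gamma-Poisson (negative binomial, variance
``mu + dispersion·mu²``) around treatment-specific expected proportions ×
library size. A latent factor gives each member taxon a log-normal
multiplier ``exp(sigma·(sqrt(rho)·z + sqrt(1-rho)·eps) - sigma²/2)`` with a
shared per-sample draw ``z``: member log-abundances then correlate at
``rho`` on the latent scale, which guarantees the monotone association that
Spearman-based planting needs, while the ``-sigma²/2`` term keeps expected
library sizes at their configured value.

All randomness flows from one seeded generator; a fixed seed yields
bit-identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AnnotatedNematodeTable, CommunityTable, annotate_nematodes
from .traits import TraitDatabase, guild_of, packaged_traits

__all__ = [
    "ConfigError",
    "LatentFactor",
    "SimulationConfig",
    "SimulatedData",
    "GradientScenario",
    "simulate_communities",
    "simulate_phosphorus_gradient",
    "expected_nematode_table",
]

#: nematode guild blocks the composition is specified over
GUILD_BLOCKS = ("Ba1", "Ba2", "Fu2", "PP", "OP")

_DEFAULT_COMPOSITION = {"Ba1": 0.10, "Ba2": 0.20, "Fu2": 0.25, "PP": 0.33, "OP": 0.12}

#: default planted-gradient schedules (fungal-dominated → bacterial-dominated)
DEFAULT_FU2_SCHEDULE = (0.40, 0.28, 0.18, 0.10)
DEFAULT_BA1_SCHEDULE = (0.04, 0.12, 0.22, 0.32)


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass(frozen=True)
class LatentFactor:
    """A planted association among taxa.

    ``taxa`` lists (kingdom, taxon-name) members; ``rho`` is the target
    pairwise correlation of member log-abundances on the latent scale
    (0 < rho <= 1); ``sigma`` is the log-scale effect SD — larger values
    make the planted signal dominate counting noise.
    """

    taxa: tuple[tuple[str, str], ...]
    rho: float = 0.9
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.rho <= 1.0:
            raise ConfigError(f"factor rho must be in (0, 1], got {self.rho}")
        if not self.sigma > 0:
            raise ConfigError(f"factor sigma must be > 0, got {self.sigma}")
        if len(self.taxa) < 2:
            raise ConfigError("a latent factor needs at least 2 member taxa")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic communities.

    Defaults mirror the emulated trial: treatments CK/P60/P120/P180 with 3
    replicates each; genus-level tables for bacteria, fungi and nematodes;
    negative-binomial dispersion 0.3 (a typical amplicon overdispersion);
    mean library size 20,000 counts per sample per kingdom.

    ``guild_composition`` maps treatment → block → proportion over the
    blocks ``Ba1, Ba2, Fu2, PP, OP`` (each block summing to 1 per
    treatment); ``None`` uses one fixed mixed composition everywhere.
    """

    treatments: tuple[str, ...] = ("CK", "P60", "P120", "P180")
    replicates: int = 3
    n_bacteria: int = 120
    n_fungi: int = 80
    guild_composition: Mapping[str, Mapping[str, float]] | None = None
    dispersion: float = 0.3
    latent_factors: tuple[LatentFactor, ...] = ()
    library_size: float = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not self.dispersion >= 0:
            raise ConfigError("dispersion must be >= 0")
        if not self.library_size > 0:
            raise ConfigError("library_size must be > 0")
        if len(set(self.treatments)) != len(self.treatments):
            raise ConfigError("treatment labels must be unique")

    def composition_for(self, treatment: str) -> dict[str, float]:
        comp = dict(_DEFAULT_COMPOSITION)
        if self.guild_composition is not None:
            if treatment not in self.guild_composition:
                raise ConfigError(f"no guild composition for treatment {treatment!r}")
            comp = {k: float(v) for k, v in self.guild_composition[treatment].items()}
        unknown = set(comp) - set(GUILD_BLOCKS)
        if unknown:
            raise ConfigError(f"unknown guild blocks: {sorted(unknown)}")
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(
                f"guild composition for {treatment!r} sums to {total}, expected 1"
            )
        if any(v < 0 for v in comp.values()):
            raise ConfigError("guild composition proportions must be nonnegative")
        return {b: comp.get(b, 0.0) for b in GUILD_BLOCKS}


@dataclass
class SimulatedData:
    """One simulated dataset: three kingdom tables, traits and metadata."""

    bacteria: CommunityTable
    fungi: CommunityTable
    nematodes: CommunityTable
    traits: TraitDatabase
    metadata: pd.DataFrame

    def annotated_nematodes(self) -> AnnotatedNematodeTable:
        return annotate_nematodes(self.nematodes, self.traits)


@dataclass
class GradientScenario:
    """A phosphorus-gradient simulation bundled with its ground truth."""

    data: SimulatedData
    config: SimulationConfig
    #: closed-form channel index implied by each treatment's composition
    expected_ci: pd.Series
    #: expected (f_bact, f_fung, f_plant) per treatment from noise-free tables
    expected_fractions: pd.DataFrame


def _block_of(record) -> str | None:
    code = guild_of(record)
    if code in ("Ba1", "Ba2", "Fu2"):
        return code
    if record.trophic_group == "PP":
        return "PP"
    if record.trophic_group == "OP":
        return "OP"
    return None  # structural BF/FF oddballs outside the composition blocks


def _nematode_pool(traits: TraitDatabase) -> dict[str, list[str]]:
    pool: dict[str, list[str]] = {b: [] for b in GUILD_BLOCKS}
    for rec in traits.records():
        block = _block_of(rec)
        if block is not None:
            pool[block].append(rec.genus)
    return pool


def _rank_abundance(n: int, decay: float = 0.9) -> np.ndarray:
    """Power-law rank-abundance base proportions, the usual long-tailed shape."""
    w = (np.arange(n) + 1.0) ** (-decay)
    return w / w.sum()


def _nematode_proportions(
    config: SimulationConfig, traits: TraitDatabase
) -> tuple[list[str], dict[str, np.ndarray]]:
    pool = _nematode_pool(traits)
    genera: list[str] = [g for b in GUILD_BLOCKS for g in pool[b]]
    per_treatment: dict[str, np.ndarray] = {}
    for trt in config.treatments:
        comp = config.composition_for(trt)
        p = np.zeros(len(genera))
        offset = 0
        for block in GUILD_BLOCKS:
            members = pool[block]
            share = comp[block]
            if share > 0 and not members:
                raise ConfigError(
                    f"guild block {block!r} has proportion {share} but no genera "
                    "in the trait pool"
                )
            if members:
                p[offset : offset + len(members)] = share * _rank_abundance(
                    len(members), decay=0.7
                )
            offset += len(members)
        per_treatment[trt] = p
    return genera, per_treatment


def _draw_counts(
    rng: np.random.Generator,
    mu: np.ndarray,
    dispersion: float,
    factor_member: np.ndarray | None = None,
) -> np.ndarray:
    """Gamma-Poisson counts around ``mu``; factor members are Poisson only.

    A taxon carrying a planted latent factor already has log-normal
    intensity heterogeneity from the factor multiplier (log-normal-Poisson
    is itself an overdispersed count model); stacking the independent gamma
    stage on top would double-count its dispersion and attenuate the
    planted correlation below the nominal ``rho``.
    """
    mu = np.maximum(mu, 0.0)
    if dispersion > 0:
        lam = rng.gamma(1.0 / dispersion, dispersion * mu)
    else:
        lam = mu.copy()
    if factor_member is not None and factor_member.any():
        lam[factor_member] = mu[factor_member]
    return rng.poisson(lam)


def simulate_communities(
    config: SimulationConfig | None = None, seed: int | None = None
) -> SimulatedData:
    """Draw one full dataset (bacteria, fungi, nematodes, traits, metadata).

    ``seed`` overrides ``config.seed``; with either fixed the output is
    bit-identical across runs.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    traits = packaged_traits()

    bact_taxa = [f"Bacterium_{i + 1:03d}" for i in range(config.n_bacteria)]
    fung_taxa = [f"Fungus_{i + 1:03d}" for i in range(config.n_fungi)]
    nema_taxa, nema_props = _nematode_proportions(config, traits)

    base_props = {
        "bacteria": (bact_taxa, _rank_abundance(config.n_bacteria)),
        "fungi": (fung_taxa, _rank_abundance(config.n_fungi)),
    }
    index_of = {
        kingdom: {t: i for i, t in enumerate(taxa)}
        for kingdom, (taxa, _) in base_props.items()
    }
    index_of["nematodes"] = {t: i for i, t in enumerate(nema_taxa)}
    member_mask = {
        "bacteria": np.zeros(config.n_bacteria, dtype=bool),
        "fungi": np.zeros(config.n_fungi, dtype=bool),
        "nematodes": np.zeros(len(nema_taxa), dtype=bool),
    }
    for factor in config.latent_factors:
        for kingdom, taxon in factor.taxa:
            if kingdom not in index_of or taxon not in index_of[kingdom]:
                raise ConfigError(f"latent factor names unknown taxon {kingdom}:{taxon}")
            member_mask[kingdom][index_of[kingdom][taxon]] = True

    samples, sample_trt, sample_rep = [], [], []
    for trt in config.treatments:
        for rep in range(1, config.replicates + 1):
            samples.append(f"{trt}_r{rep}")
            sample_trt.append(trt)
            sample_rep.append(rep)
    meta = pd.DataFrame(
        {"treatment": sample_trt, "replicate": sample_rep},
        index=pd.Index(samples, name="sample_id"),
    )

    counts = {
        "bacteria": np.zeros((len(samples), config.n_bacteria), dtype=int),
        "fungi": np.zeros((len(samples), config.n_fungi), dtype=int),
        "nematodes": np.zeros((len(samples), len(nema_taxa)), dtype=int),
    }
    for s_idx, sample in enumerate(samples):
        trt = meta.loc[sample, "treatment"]
        mus = {
            "bacteria": base_props["bacteria"][1] * config.library_size,
            "fungi": base_props["fungi"][1] * config.library_size,
            "nematodes": nema_props[trt] * config.library_size,
        }
        log_delta = {k: np.zeros_like(v) for k, v in mus.items()}
        for factor in config.latent_factors:
            z = rng.standard_normal()
            for kingdom, taxon in factor.taxa:
                eps = rng.standard_normal()
                effect = factor.sigma * (
                    np.sqrt(factor.rho) * z + np.sqrt(1.0 - factor.rho) * eps
                )
                log_delta[kingdom][index_of[kingdom][taxon]] += (
                    effect - factor.sigma**2 / 2.0
                )
        for kingdom in ("bacteria", "fungi", "nematodes"):
            mu = mus[kingdom] * np.exp(log_delta[kingdom])
            counts[kingdom][s_idx] = _draw_counts(
                rng, mu, config.dispersion, member_mask[kingdom]
            )

    def _table(kingdom: str, taxa: Sequence[str]) -> CommunityTable:
        return CommunityTable(
            pd.DataFrame(counts[kingdom], index=meta.index.copy(), columns=list(taxa))
        )

    return SimulatedData(
        bacteria=_table("bacteria", bact_taxa),
        fungi=_table("fungi", fung_taxa),
        nematodes=_table("nematodes", nema_taxa),
        traits=traits,
        metadata=meta,
    )


def expected_nematode_table(config: SimulationConfig) -> CommunityTable:
    """Noise-free expected nematode counts (one row per treatment).

    Useful for parameter-recovery checks: indices computed on this table
    equal the closed-form values implied by the guild composition.
    """
    traits = packaged_traits()
    genera, props = _nematode_proportions(config, traits)
    rows = {trt: props[trt] * config.library_size for trt in config.treatments}
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=genera)
    frame.index.name = "sample_id"
    return CommunityTable(frame)


def expected_channel_index(config: SimulationConfig, treatment: str) -> float:
    """Closed-form CI implied by a treatment's guild composition.

    CI = 100·0.8·Fu2/(3.2·Ba1 + 0.8·Fu2) on the block shares (library size
    cancels).
    """
    comp = config.composition_for(treatment)
    fu2 = 0.8 * comp["Fu2"]
    ba1 = 3.2 * comp["Ba1"]
    if fu2 + ba1 == 0:
        return float("nan")
    return 100.0 * fu2 / (fu2 + ba1)


def simulate_phosphorus_gradient(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    fu2_schedule: Sequence[float] = DEFAULT_FU2_SCHEDULE,
    ba1_schedule: Sequence[float] = DEFAULT_BA1_SCHEDULE,
) -> GradientScenario:
    """Simulate the planted decomposition-channel gradient.

    Across the treatment schedule the Fu2 share falls and the Ba1 share
    rises (fungal-channel dominance at low phosphorus giving way to the
    bacterial channel), so the channel index CI decreases in expectation
    and ternary energy-flow points drift from the fungal toward the
    bacterial vertex. The schedules must be monotone in those directions
    (or entirely flat, for null simulations).
    """
    from .footprints import group_footprints  # local import to avoid cycle
    from .energyflow import channel_fractions

    base = config or SimulationConfig()
    if len(fu2_schedule) != len(base.treatments) or len(ba1_schedule) != len(
        base.treatments
    ):
        raise ConfigError("schedules must give one share per treatment")
    fu2 = [float(v) for v in fu2_schedule]
    ba1 = [float(v) for v in ba1_schedule]
    flat = all(a == fu2[0] for a in fu2) and all(b == ba1[0] for b in ba1)
    monotone = all(a >= b for a, b in zip(fu2, fu2[1:])) and all(
        a <= b for a, b in zip(ba1, ba1[1:])
    )
    if not (flat or monotone):
        raise ConfigError(
            "channel-dominance schedule must be monotone (Fu2 non-increasing, "
            "Ba1 non-decreasing) or entirely flat"
        )
    if base.replicates < 2:
        warnings.warn(
            "single-replicate scenario: tables are emitted but network "
            "inference is disabled (correlation needs replication)",
            stacklevel=2,
        )

    composition = {}
    for trt, f, b in zip(base.treatments, fu2, ba1):
        rest = 1.0 - f - b
        if rest <= 0:
            raise ConfigError("Fu2 + Ba1 shares leave no room for the other blocks")
        # split the remainder over Ba2/PP/OP in fixed ratio
        composition[trt] = {
            "Ba1": b,
            "Fu2": f,
            "Ba2": rest * 0.30,
            "PP": rest * 0.50,
            "OP": rest * 0.20,
        }
    config = replace(base, guild_composition=composition)
    data = simulate_communities(config, seed=seed)

    expected_ci = pd.Series(
        {trt: expected_channel_index(config, trt) for trt in config.treatments},
        name="expected_CI",
    )
    expected = expected_nematode_table(config)
    ann = annotate_nematodes(expected, data.traits)
    fp = group_footprints(ann, absolute_counts=True)
    frac_rows = {}
    for trt in config.treatments:
        row = fp.loc[trt]
        frac_rows[trt] = channel_fractions(row["BFMF"], row["FFMF"], row["PPMF"])
    expected_fractions = pd.DataFrame.from_dict(
        frac_rows, orient="index", columns=["f_bact", "f_fung", "f_plant"]
    )
    return GradientScenario(
        data=data,
        config=config,
        expected_ci=expected_ci,
        expected_fractions=expected_fractions,
    )
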
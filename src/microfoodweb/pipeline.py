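"""One-command orchestration: tables in, results bundle out.

``run_all`` wires the stages together — diversity → faunal indices →
metabolic footprints → energy flow → co-occurrence networks — and writes a
results bundle (seven TSV/JSON artifacts) plus a run manifest recording
input hashes, the config snapshot, per-stage row counts and warnings.
Stages that cannot run (footprints on relative abundances, networks
without enough samples) are *skipped with an explicit manifest entry*,
never silently. Outputs are pure functions of (inputs, config, seed):
re-running the same config reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diversity import alpha_diversity
from .energyflow import ternary_table
from .faunal import DEFAULT_WEIGHTS, FaunalWeights, faunal_index_table
from .footprints import auto_k, functional_footprint, group_footprints
from .io import (
    CommunityTable,
    annotate_nematodes,
    read_community_table,
    read_metadata,
    validate_metadata,
)
from .network import join_kingdoms, network_summary, prevalence_filter, spearman_edges
from .simulate import SimulationConfig, simulate_communities, simulate_phosphorus_gradient
from .traits import load_trait_table

__all__ = ["RunConfig", "PipelineError", "load_run_config", "run_all"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage could not run; the message names the blocked stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``scenario`` names a simulation (``"communities"`` or
    ``"gradient"``), or the five input paths point at real tables. For file
    inputs ``absolute_counts`` must be asserted for the footprint stages to
    run; simulated tables are counts by construction.
    """

    scenario: str | None = None
    bacteria: str | None = None
    fungi: str | None = None
    nematodes: str | None = None
    traits: str | None = None
    metadata: str | None = None
    absolute_counts: bool = False
    seed: int = 0
    min_prevalence: int = 3
    r_threshold: float = 0.6
    p_threshold: float = 0.05
    p_method: str = "t_approx"
    k: float | None = None  # None = auto (max footprint / 50)
    include_cp1: bool = True
    weights_file: str | None = None


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"unknown run-config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write the results bundle into ``outdir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counter = _WarningCounter()
    root = logging.getLogger("microfoodweb")
    root.addHandler(counter)
    try:
        return _run_all(config, outdir, counter)
    finally:
        root.removeHandler(counter)


def _run_all(config: RunConfig, outdir: Path, counter: _WarningCounter) -> dict:
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
        "warnings": [],
    }
    stages = manifest["stages"]

    # ---- stage: inputs -------------------------------------------------
    absolute_counts = config.absolute_counts
    if config.scenario is not None:
        if config.scenario == "gradient":
            scenario = simulate_phosphorus_gradient(seed=config.seed)
            data = scenario.data
        elif config.scenario == "communities":
            data = simulate_communities(SimulationConfig(seed=config.seed))
        else:
            raise PipelineError(f"inputs: unknown scenario {config.scenario!r}")
        bacteria, fungi, nematodes = data.bacteria, data.fungi, data.nematodes
        traits, metadata = data.traits, data.metadata
        absolute_counts = True  # simulated tables are counts by construction
        manifest["inputs"]["scenario"] = config.scenario
    else:
        needed = {"bacteria": config.bacteria, "fungi": config.fungi,
                  "nematodes": config.nematodes}
        missing = [k for k, v in needed.items() if v is None]
        if missing:
            raise PipelineError(f"inputs: missing table paths {missing}")
        if config.traits is None:
            raise PipelineError(
                "faunal_indices: blocked — no trait table configured "
                "(set 'traits' to a genus trait TSV)"
            )
        bacteria = read_community_table(config.bacteria)
        fungi = read_community_table(config.fungi)
        nematodes = read_community_table(config.nematodes)
        traits = load_trait_table(config.traits)
        metadata = None
        if config.metadata is not None:
            metadata = read_metadata(config.metadata)
            for tbl in (bacteria, fungi, nematodes):
                validate_metadata(tbl, metadata)
        for name, path in {**needed, "traits": config.traits,
                           "metadata": config.metadata}.items():
            if path is not None:
                manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}
    stages["inputs"] = {"status": "ok", "samples": len(nematodes.samples)}

    weights = (
        FaunalWeights.from_yaml(config.weights_file)
        if config.weights_file
        else DEFAULT_WEIGHTS
    )

    # ---- stage: diversity ----------------------------------------------
    frames = []
    for kingdom, tbl in (("bacteria", bacteria), ("fungi", fungi), ("nematodes", nematodes)):
        div = alpha_diversity(tbl).reset_index()
        div.insert(0, "kingdom", kingdom)
        frames.append(div)
    diversity = pd.concat(frames, ignore_index=True)
    diversity.to_csv(outdir / "diversity.tsv", sep="\t", index=False, na_rep="NA")
    stages["diversity"] = {"status": "ok", "rows": len(diversity)}

    # ---- stage: faunal_indices ------------------------------------------
    annotated = annotate_nematodes(nematodes, traits)
    indices = faunal_index_table(annotated, weights=weights, include_cp1=config.include_cp1)
    indices.to_csv(outdir / "indices.tsv", sep="\t", na_rep="NA")
    stages["faunal_indices"] = {
        "status": "ok",
        "rows": len(indices),
        "unmatched_genera": list(annotated.unmatched),
    }

    # ---- stage: footprints ----------------------------------------------
    if absolute_counts:
        fp = group_footprints(annotated, absolute_counts=True)
        k = config.k if config.k is not None else auto_k(fp["Fe"], fp["Fs"])
        areas = []
        for sample in fp.index:
            si, ei = indices.loc[sample, "SI"], indices.loc[sample, "EI"]
            if pd.notna(si) and pd.notna(ei):
                areas.append(
                    functional_footprint(si, ei, fp.loc[sample, "Fe"],
                                         fp.loc[sample, "Fs"], k).area
                )
            else:
                areas.append(float("nan"))
        fp["diamond_area"] = areas
        fp["k"] = k
        fp.to_csv(outdir / "footprints.tsv", sep="\t", index_label="sample_id", na_rep="NA")
        stages["footprints"] = {"status": "ok", "rows": len(fp), "k": k}

        ternary = ternary_table(fp)
        ternary.to_csv(outdir / "ternary.tsv", sep="\t", na_rep="NA")
        stages["energy_flow"] = {"status": "ok", "rows": len(ternary)}
    else:
        reason = (
            "table not asserted to hold absolute counts; footprints are "
            "linear in abundance and refuse proportions"
        )
        stages["footprints"] = {"status": "skipped", "reason": reason}
        stages["energy_flow"] = {"status": "skipped", "reason": "requires footprints"}

    # ---- stage: network --------------------------------------------------
    if len(nematodes.samples) >= 4:
        filtered = {
            name: prevalence_filter(tbl, config.min_prevalence)
            for name, tbl in (("bacteria", bacteria), ("fungi", fungi),
                              ("nematodes", nematodes))
        }
        joined, kingdom_of = join_kingdoms(**filtered)
        edges = spearman_edges(
            joined,
            r_threshold=config.r_threshold,
            p_threshold=config.p_threshold,
            p_method=config.p_method,
            kingdoms=kingdom_of,
            seed=config.seed,
        )
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        stats = network_summary(edges)
        pd.DataFrame([dataclasses.asdict(stats)]).to_csv(
            outdir / "stats.tsv", sep="\t", index=False, na_rep="NA"
        )
        stages["network"] = {"status": "ok", "edges": stats.total_links,
                             "nodes": stats.n_nodes}
    else:
        stages["network"] = {
            "status": "skipped",
            "reason": "fewer than 4 samples; correlation-based inference disabled",
        }

    manifest["warnings"] = counter.messages
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
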
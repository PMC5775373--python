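"""End-to-end orchestration: describe -> motifs -> sample -> sweep -> diversity.

One :class:`RunConfig` (built in code or loaded from YAML) drives every
stage; a run manifest records the config, seed, package version, and a
SHA-256 checksum per output file, so identical configs are verifiably
reproducible. Stage outputs are TSVs with a self-describing comment header
carrying the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .descriptive_stats import fractions_frame, summary_frame
from .diversity_estimator import required_counts_table
from .exceptions import AlteredSelfError, ParameterError
from .motif_analysis import SpecificityScheme, motif_change_summary, motif_density_table
from .repertoire_io import (
    EpitopeMap,
    RepertoirePair,
    filter_ninemers,
    load_peptide_table,
    restrict_repertoire,
    write_peptide_table,
)
from .sampling_model import (
    DEFAULT_P_GRID,
    SamplingConfig,
    derive_seed,
    run_sampling,
    specificity_sweep,
)
from .synthetic_data import GeneratorParams, generate_repertoire_pair

logger = logging.getLogger("alteredself")

STAGES = ("simulate", "describe", "motifs", "sample", "sweep", "diversity")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one of input_path / generator)."""

    outdir: str
    input_path: Optional[str] = None
    generator: Optional[GeneratorParams] = None
    epitope_map_path: Optional[str] = None
    pool_mode: str = "kir_epitopes"
    schemes: tuple[str, ...] = ("exact_pair", "physchem_group")
    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    sample_p: float = 1.0 / 400.0
    replicates: int = 10_000
    seed: int = 0
    tol: float = 1e-9
    empty_policy: str = "redraw"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ParameterError("exactly one of input_path or generator must be set")
        if any(not (0.0 < p <= 1.0) for p in self.p_grid):
            raise ParameterError("all p-grid values must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        gen = raw.pop("generator", None)
        if gen is not None:
            gen = GeneratorParams(**gen)
        for key in ("schemes", "p_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(generator=gen, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            gen = dataclasses.asdict(self.generator)
            gen["length_distribution"] = {int(k): v for k, v in gen["length_distribution"].items()}
            d["generator"] = gen
        return d

    def config_hash(self) -> str:
        # outdir is excluded: the hash identifies the analysis, not its location
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# alteredself {__version__} stage={stage} config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the manifest (also written to manifest.json)."""
    outdir = Path(config.outdir)
    if config.input_path is not None and not Path(config.input_path).exists():
        raise ParameterError(f"input path does not exist: {config.input_path}")
    if config.epitope_map_path is not None and not Path(config.epitope_map_path).exists():
        raise ParameterError(f"epitope map path does not exist: {config.epitope_map_path}")
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": chash,
        "version": __version__,
        "seed": config.seed,
        "outputs": {},
        "stages_completed": [],
        "counts": {},
    }
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        emap = (
            EpitopeMap.from_tsv(config.epitope_map_path)
            if config.epitope_map_path
            else EpitopeMap.default()
        )

        stage = "simulate"
        if config.generator is not None:
            pair = generate_repertoire_pair(config.generator)
            input_tsv = outdir / "input_repertoire.tsv"
            write_peptide_table(pair, input_tsv)
            outputs["input_repertoire"] = input_tsv
        else:
            pair = load_peptide_table(config.input_path)
        manifest["stages_completed"].append(stage)
        manifest["counts"]["peptides"] = len(pair)
        logger.info("loaded %d unique peptides for %s", len(pair), pair.cell_line_id)

        restricted = restrict_repertoire(pair, emap, mode=config.pool_mode)

        stage = "describe"
        _write_tsv(summary_frame(restricted), outdir / "summary.tsv", stage, chash)
        _write_tsv(fractions_frame(restricted), outdir / "hla_fractions.tsv", stage, chash)
        outputs["summary"] = outdir / "summary.tsv"
        outputs["hla_fractions"] = outdir / "hla_fractions.tsv"
        manifest["stages_completed"].append(stage)
        manifest["counts"].update(
            n_H=restricted.n_H, n_HI=restricted.n_HI, n_MV=restricted.n_MV
        )

        stage = "motifs"
        ninemers = filter_ninemers(restricted)
        summary_rows = []
        for scheme_name in config.schemes:
            scheme = SpecificityScheme.by_name(scheme_name)
            table = motif_density_table(ninemers, scheme)
            _write_tsv(
                table.to_frame(tol=config.tol),
                outdir / f"motif_table_{scheme_name}.tsv",
                stage,
                chash,
            )
            outputs[f"motif_table_{scheme_name}"] = outdir / f"motif_table_{scheme_name}.tsv"
            summary_rows.append(motif_change_summary(table, tol=config.tol).to_row())
            manifest["counts"][f"N_P7P8_{scheme_name}"] = table.n_motifs
        _write_tsv(pd.DataFrame(summary_rows), outdir / "motif_summary.tsv", stage, chash)
        outputs["motif_summary"] = outdir / "motif_summary.tsv"
        manifest["stages_completed"].append(stage)

        stage = "sample"
        sample_cfg = SamplingConfig(
            p=config.sample_p,
            replicates=config.replicates,
            seed=derive_seed(config.seed, 1000),
            pool_mode="all",  # restriction already applied above
            empty_policy=config.empty_policy,
            tol=config.tol,
        )
        result = run_sampling(restricted, sample_cfg)
        _write_tsv(result.replicates_frame(), outdir / "sampling_replicates.tsv", stage, chash)
        _write_tsv(
            pd.DataFrame([result.summary_row()]), outdir / "sampling_summary.tsv", stage, chash
        )
        outputs["sampling_replicates"] = outdir / "sampling_replicates.tsv"
        outputs["sampling_summary"] = outdir / "sampling_summary.tsv"
        manifest["stages_completed"].append(stage)
        manifest["counts"]["replicates"] = config.replicates

        stage = "sweep"
        sweep = specificity_sweep(
            restricted,
            p_values=config.p_grid,
            replicates=config.replicates,
            seed=config.seed,
            pool_mode="all",
            empty_policy=config.empty_policy,
            tol=config.tol,
        )
        _write_tsv(sweep, outdir / "sweep.tsv", stage, chash)
        outputs["sweep"] = outdir / "sweep.tsv"
        manifest["stages_completed"].append(stage)

        stage = "diversity"
        diversity = required_counts_table(sweep)
        _write_tsv(diversity, outdir / "diversity.tsv", stage, chash)
        outputs["diversity"] = outdir / "diversity.tsv"
        manifest["stages_completed"].append(stage)
    except AlteredSelfError as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest["outputs"] = {name: _sha256(p) for name, p in outputs.items()}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise AlteredSelfError(f"stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {name: _sha256(path) for name, path in outputs.items()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def read_stage_tsv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline stage TSV, skipping the self-describing header comment."""
    return pd.read_csv(path, sep="\t", comment="#")
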
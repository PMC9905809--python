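"""End-to-end design pipeline with a reproducible run directory.

Wires the stages in order: preprocess the template structure, define the
groove, align the groove and base alleles, build the substitution set,
enumerate and score all 2^N variants, compute enrichment scores, and prune
to the minimal set.  Every artifact carries the configuration hash so a
rerun with an identical configuration is bit-identical under the internal
scorer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import design, sampling, structio
from .design import AlleleSequence
from .energy import EnergyParams, InternalScorer

log = logging.getLogger("mhcgraft")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """All thresholds and paths of one design run.

    Defaults are the workflow's canonical constants: 4 Angstrom contact
    threshold, 5 Angstrom groove cutoff, 3.5 Angstrom stricter cutoff at
    dual peptide/TCR positions, 10% classification cutoff, top 2.5% pool,
    0.5 enrichment threshold for the minimal set.
    """

    template_path: str = ""
    heavy_chain: str = "A"
    peptide_chain: str = "C"
    groove_fasta: str = ""
    base_fasta: str = ""
    out_dir: str = "run"
    groove_span: int = 180
    contact_threshold: float = 4.0
    groove_cutoff: float = 5.0
    ptb_cutoff: float = 3.5
    class_cutoff: float = 10.0
    top_fraction: float = 0.025
    theta_enrich: float = 0.5
    seed: int = 0
    energy: dict = field(default_factory=dict)
    classes: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("contact_threshold", "groove_cutoff", "ptb_cutoff", "class_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("top_fraction", "theta_enrich"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.groove_span <= 0:
            raise ValueError("groove_span must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and completed artifacts."""

    def __init__(self, stage: str, message: str, artifacts: list[str]) -> None:
        super().__init__(f"stage {stage!r} failed: {message}; completed artifacts: {artifacts}")
        self.stage = stage
        self.artifacts = artifacts


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML configuration; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)} (known: {sorted(known)})")
    if "classes" in data:
        data["classes"] = {int(k): v for k, v in data["classes"].items()}
    return RunConfig(**data)


def _write_tsv(path: Path, header: list[str], rows: list[list], config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(
    config: RunConfig,
    template: structio.ProcessedTemplate | None = None,
    groove_allele: AlleleSequence | None = None,
    base_allele: AlleleSequence | None = None,
) -> dict:
    """Execute the full design workflow; returns a result dict and writes
    artifacts (groove TSV, substitutions, ranked variants, enrichment,
    minimal set, run manifest) under ``config.out_dir``.

    The three heavyweight inputs can be passed in-memory (fixtures, tests)
    or read from the configured paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    artifacts: list[str] = []
    stage = "load-inputs"
    try:
        if template is None:
            model = structio.read_structure(config.template_path)
            template = structio.preprocess_template(
                model, config.heavy_chain, config.peptide_chain, config.groove_span
            )
        if groove_allele is None:
            groove_allele = design.read_fasta(config.groove_fasta)[0]
        if base_allele is None:
            base_allele = design.read_fasta(config.base_fasta)[0]

        stage = "preprocess"
        structio.write_pdb(template, out / "template.pdb")
        artifacts.append(str(out / "template.pdb"))
        log.info("template %s: groove %d residues, peptide %d",
                 template.source_id, len(template.groove), len(template.peptide))

        stage = "groove"
        groove = design.define_groove(template, cutoff=config.groove_cutoff)
        _write_tsv(
            out / "groove.tsv",
            ["position", "min_dist_A", "in_groove"],
            [[p, f"{groove.min_dist[p]:.3f}", int(p in groove.positions)]
             for p in sorted(groove.min_dist)],
            chash,
        )
        artifacts.append(str(out / "groove.tsv"))

        stage = "align"
        mapping = design.align_pair(groove_allele, base_allele)

        stage = "substitutions"
        subs = design.build_substitutions(groove, groove_allele, base_allele, mapping)
        _write_tsv(
            out / "substitutions.tsv",
            ["position", "from", "to", "min_dist_A", "class_change"],
            [[s.position, s.from_aa, s.to_aa, f"{s.min_dist:.3f}", int(s.class_change)]
             for s in subs],
            chash,
        )
        artifacts.append(str(out / "substitutions.tsv"))
        log.info("groove %d positions, %d substitutions: %s",
                 len(groove.positions), len(subs), design.format_substitutions(subs))

        stage = "score"
        params = EnergyParams.from_dict(config.energy) if config.energy else EnergyParams()
        base_groove_seq = base_allele.seq[: len(template.groove)]
        ranked = sampling.score_all(
            template, base_groove_seq, subs, params=params, scorer=InternalScorer(params)
        )
        _write_tsv(
            out / "ranked_variants.tsv",
            ["mask_hex", "substitutions_applied", "E_bind", "E_total"],
            [[str(mask),
              design.format_substitutions(s for b, s in zip(mask.bits, subs) if b) or "-",
              f"{eb:.6f}", f"{et:.6f}"]
             for mask, eb, et in ranked.entries],
            chash,
        )
        artifacts.append(str(out / "ranked_variants.tsv"))

        stage = "enrichment"
        table = sampling.enrichment(ranked, subs, top_fraction=config.top_fraction)
        _write_tsv(
            out / "enrichment.tsv",
            ["position", "from", "to", "enrichment"],
            [[s.position, s.from_aa, s.to_aa, f"{table.score[s.position]:.6f}"] for s in subs],
            chash,
        )
        artifacts.append(str(out / "enrichment.tsv"))

        stage = "minimal-set"
        kept = design.minimal_set(
            subs, table.score, classes=config.classes, groove=groove,
            theta_enrich=config.theta_enrich, ptb_cutoff=config.ptb_cutoff,
        )
        chimera = design.apply_substitutions(base_allele, kept, groove_allele)
        manifest = {
            "config_hash": chash,
            "template": template.source_id,
            "groove_allele": groove_allele.name,
            "base_allele": base_allele.name,
            "chimera_name": chimera.name,
            "n_groove_positions": len(groove.positions),
            "n_substitutions": len(subs),
            "n_variants": len(ranked.entries),
            "pool_size": table.pool_size,
            "minimal_set": [str(s) for s in kept],
            "chimera_seq": chimera.chimera_seq,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        artifacts.append(str(out / "manifest.json"))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc), artifacts) from exc

    return {
        "groove": groove,
        "substitutions": subs,
        "ranked": ranked,
        "enrichment": table,
        "minimal_set": kept,
        "chimera": chimera,
        "manifest": manifest,
        "artifacts": artifacts,
    }
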
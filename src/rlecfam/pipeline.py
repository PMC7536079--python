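"""End-to-end orchestration: generate/ingest -> decompose -> classify ->
catalogue -> slippage -> splice -> truth comparison, with a reproducible
run manifest.

Stages write plain TSV/JSON/newick reports into the output directory; logs
go to stderr and are never mixed into report files.  A single seed in the
config is propagated to per-stage child seeds by a fixed derivation so that
stage-level reruns reproduce pipeline runs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import classify as cl
from . import patterns as pt
from . import repeats as rp
from . import seqio as sio
from . import slippage as sl
from . import splicing as sp
from .simulate import Family, FamilyConfig, generate_family, truth_compare

log = logging.getLogger("rlecfam")

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs (or a generate-block), thresholds, outputs and the seed."""

    outdir: str = "rlecfam_out"
    seed: int = 0
    # either explicit inputs ...
    transcripts: Optional[str] = None
    genomic: Optional[str] = None
    gff3: Optional[str] = None
    truth: Optional[str] = None
    # ... or a generate-block of FamilyConfig fields
    generate: Optional[dict] = None
    # thresholds
    unit_min_identity: float = 0.8
    detect_threshold: float = 0.8
    slip_min_identity: float = 0.9
    bootstrap_reps: int = 1000
    allowed_unit_lengths: tuple[int, ...] = (30, 33)
    anchor: Optional[tuple[str, int]] = None
    within_type_only: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.transcripts is None and self.generate is None:
            raise ValueError(
                "config needs input paths or a generate-block (it has neither)"
            )
        if not (0 < self.unit_min_identity <= 1):
            raise ValueError("unit_min_identity must be in (0, 1]")
        if not (0 < self.slip_min_identity <= 1):
            raise ValueError("slip_min_identity must be in (0, 1]")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "anchor" in data and data["anchor"] is not None:
            data["anchor"] = tuple(data["anchor"])
        if "allowed_unit_lengths" in data:
            data["allowed_unit_lengths"] = tuple(data["allowed_unit_lengths"])
        return cls(**data)

    def canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=list)


def _stage_seed(seed: int, stage_index: int) -> int:
    return (seed * 7919 + stage_index) % (2**31)


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(levelname)s %(name)s: %(message)s")
    )
    log.handlers[:] = [handler]
    log.setLevel(level)


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages; returns objects and report paths.

    Any stage failure aborts with the stage name and cause; reports written
    by earlier stages are retained.
    """
    setup_logging(config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"paths": {}}

    # ---- stage: generate / ingest ----------------------------------------
    stage = "generate" if config.generate is not None else "ingest"
    try:
        family: Optional[Family] = None
        truth: Optional[dict] = None
        models: list[sio.GeneModel] = []
        anchor = config.anchor
        if config.generate is not None:
            gen = dict(config.generate)
            gen.setdefault("seed", _stage_seed(config.seed, 0))
            family = generate_family(FamilyConfig(**gen))
            paths = family.write(outdir / "inputs")
            results["paths"].update(
                {k: str(v) for k, v in paths.items()}
            )
            transcripts = family.transcripts()
            models = family.gene_models()
            truth = family.truth
            if anchor is None:
                anchor = family.anchor
        else:
            transcripts = sio.read_fasta(config.transcripts)
            if config.genomic and config.gff3:
                genomic = sio.read_fasta(config.genomic)
                models = sio.read_gff3(config.gff3, genomic)
            if config.truth:
                truth = json.loads(Path(config.truth).read_text())
                if anchor is None and "anchor" in truth:
                    anchor = (truth["anchor"][0], int(truth["anchor"][1]))
        results["family"] = family
        results["truth"] = truth
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- stage: decompose --------------------------------------------------
    try:
        records = [sio.annotate_transcript(t) for t in transcripts]
        cds_list = [
            sio.NucSequence(r.id, r.cdna.seq[r.orf_span[0] : r.orf_span[1]])
            for r in records
            if r.orf_len >= 6
        ]
        arrays = rp.decompose_family(
            cds_list,
            min_identity=config.unit_min_identity,
            allowed_unit_lengths=config.allowed_unit_lengths,
            detect_threshold=config.detect_threshold,
        )
        by_id = {a.source_id: a for a in arrays}
        for r in records:
            r.repeat_array = by_id.get(r.id)
        rp.arrays_to_tsv(arrays, outdir / "repeats.tsv")
        rp.arrays_to_json(arrays, outdir / "repeats.json")
        results["records"] = records
        results["arrays"] = by_id
        results["paths"]["repeats_tsv"] = str(outdir / "repeats.tsv")
        results["paths"]["repeats_json"] = str(outdir / "repeats.json")
    except Exception as exc:
        raise PipelineError("decompose", exc) from exc

    # ---- stage: classify ----------------------------------------------------
    try:
        motifs: dict[str, Optional[str]] = {}
        masked: dict[str, str] = {}
        for r in records:
            if not r.protein:
                motifs[r.id] = None
                continue
            try:
                mp = cl.mask_repeats(r.protein, r.repeat_array, snap=True)
            except cl.MaskError:
                mp = r.protein
            masked[r.id] = mp
            if anchor is not None:
                a = cl.extract_motif(mp, anchor, r.id)
                motifs[r.id] = a.motif if a else None
                r.motif = motifs[r.id]
            else:
                motifs[r.id] = None
        assignments = [
            cl.MotifAssignment(rid, m, 1, m) if m else None
            for rid, m in motifs.items()
        ]
        type_table = cl.assign_types(assignments)
        copy_numbers = {
            a.source_id: a.copy_number for a in arrays
        }
        cl.types_to_tsv(type_table, outdir / "types.tsv", copy_numbers)
        results["motifs"] = motifs
        results["type_table"] = type_table
        results["paths"]["types_tsv"] = str(outdir / "types.tsv")

        tree = None
        typed = [rid for rid, m in motifs.items() if m]
        if len(typed) >= 3:
            aln = cl.align_proteins([masked[rid] for rid in typed])
            tree = cl.bootstrap_support(
                typed, aln, n_reps=config.bootstrap_reps,
                seed=_stage_seed(config.seed, 2),
            )
            (outdir / "tree.nwk").write_text(tree.newick() + "\n")
            results["paths"]["tree"] = str(outdir / "tree.nwk")
        results["tree"] = tree
    except Exception as exc:
        raise PipelineError("classify", exc) from exc

    # ---- stage: catalog -----------------------------------------------------
    try:
        member_arrays = [a for a in arrays if a.copy_number > 0]
        cat = pt.catalog(member_arrays)
        pt.catalog_to_tsv(cat, outdir / "patterns.tsv")
        nested = pt.per_type_patterns(member_arrays, type_table)
        pt.per_type_to_tsv(nested, outdir / "patterns_by_type.tsv")
        results["catalog"] = cat
        results["paths"]["patterns_tsv"] = str(outdir / "patterns.tsv")
    except Exception as exc:
        raise PipelineError("catalog", exc) from exc

    # ---- stage: slippage ----------------------------------------------------
    try:
        events = sl.scan_family(
            member_arrays,
            type_table=type_table,
            within_type_only=config.within_type_only,
            min_identity=config.slip_min_identity,
        )
        sl.events_to_tsv(events, outdir / "slippage.tsv")
        results["slippage_events"] = events
        results["paths"]["slippage_tsv"] = str(outdir / "slippage.tsv")
    except Exception as exc:
        raise PipelineError("slippage", exc) from exc

    # ---- stage: splice ------------------------------------------------------
    try:
        splice: dict[str, list[sp.SpliceEvent]] = {}
        rows = []
        if models:
            by_model = {m.id: m for m in models}
            for t in transcripts:
                base = t.id.split("_v")[0]
                model = by_model.get(t.id) or by_model.get(base)
                if model is None:
                    continue
                try:
                    chain = sp.map_transcript(model, t)
                except sp.MappingError:
                    log.warning("%s: unmappable transcript (unsupported "
                                "splicing pattern?)", t.id)
                    continue
                evs = sp.classify_events(sp.canonical_chain(model), chain)
                splice[t.id] = evs
                for ev in evs:
                    flags = (
                        sp.shifted_site_validation(model, ev)
                        if ev.mode != "exon_skipping"
                        else None
                    )
                    rows.append((t.id, ev, flags))
            sp.splice_report_tsv(rows, outdir / "splice.tsv")
            results["paths"]["splice_tsv"] = str(outdir / "splice.tsv")
        results["splice"] = splice
    except Exception as exc:
        raise PipelineError("splice", exc) from exc

    # ---- stage: compare -----------------------------------------------------
    try:
        if truth is not None:
            report = truth_compare(
                truth,
                {
                    "arrays": {
                        k: v for k, v in by_id.items()
                        if k in truth["members"]
                    },
                    "motifs": motifs,
                    "slippage_events": events,
                    "splice": splice,
                },
            )
            (outdir / "recovery.json").write_text(json.dumps(report, indent=1))
            results["recovery"] = report
            results["paths"]["recovery"] = str(outdir / "recovery.json")
    except Exception as exc:
        raise PipelineError("compare", exc) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            config.canonical_json().encode()
        ).hexdigest(),
        "outputs": sorted(results["paths"].values()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["paths"]["manifest"] = str(outdir / "manifest.json")
    return results
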
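"""Orchestration: simulate -> translate -> scan -> call -> matrix -> gain/loss.

One reproducible run over a set of genomes, with a machine-readable manifest
(parameters, input checksums, package version) so every output is traceable.
All randomness flows from the single seed in the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

from . import __version__
from .datasets import mammal_tree, table2_matrix
from .dollo import EventMap, SpeciesTree, infer_events, lineage_summary, parse_tree
from .hmm import ProfileHMM, build_profile, scan
from .loci import (
    DEFAULT_FRAMESHIFT_GAP,
    DEFAULT_FULL_SPAN_STATES,
    DEFAULT_MERGE_WINDOW,
    DEFAULT_MIN_IDENTITY,
    Locus,
    assign_family,
    call_loci,
    classify_locus,
    write_loci_gff3,
    write_locus_tsv,
)
from .matrix import PresenceMatrix, build_matrix, read_matrix, write_matrix
from .sixframe import translate_six_frames
from .synthetic import ReferenceSet

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "survey_genome", "run_survey", "run_table2"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for actionable error messages."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, thresholds and the mandatory seed for one pipeline run."""

    genome_fastas: dict[str, Path] = field(default_factory=dict)  # species -> FASTA
    reference_alignment: Path | None = None
    tree: Path | None = None
    matrix: Path | None = None
    out_dir: Path = Path("homeodyn_out")
    bit_threshold: float = 15.0
    min_envelope: int = 12
    min_identity: float = DEFAULT_MIN_IDENTITY
    match_occupancy_threshold: float = 0.5
    pseudocount: float = 1.0
    merge_window: int = DEFAULT_MERGE_WINDOW
    full_span_states: int = DEFAULT_FULL_SPAN_STATES
    frameshift_gap: int = DEFAULT_FRAMESHIFT_GAP
    seed: int = 0
    focal: tuple[str, str] = ("human", "mouse")

    def validate(self) -> None:
        if not (0 < self.match_occupancy_threshold <= 1):
            raise PipelineError("config", "match_occupancy_threshold outside (0, 1]")
        if not (0 <= self.min_identity <= 1):
            raise PipelineError("config", "min_identity outside [0, 1]")
        if self.merge_window < 0 or self.min_envelope < 1:
            raise PipelineError("config", "negative window or envelope")


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def survey_genome(
    sequences: Mapping[str, str],
    hmm: ProfileHMM,
    references: ReferenceSet,
    species: str | None = None,
    bit_threshold: float = 15.0,
    min_envelope: int = 12,
    merge_window: int = DEFAULT_MERGE_WINDOW,
    full_span_states: int = DEFAULT_FULL_SPAN_STATES,
    frameshift_gap: int = DEFAULT_FRAMESHIFT_GAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[Locus]:
    """Scan one genome's sequences and return classified, family-assigned loci."""
    all_hits = []
    for seq_id, seq in sequences.items():
        frames = translate_six_frames(seq, seq_id)
        all_hits.extend(
            scan(hmm, frames, bit_threshold, min_envelope, genome=species)
        )
    loci = call_loci(
        all_hits,
        merge_window=merge_window,
        genome=dict(sequences),
        full_span_states=full_span_states,
        frameshift_gap=frameshift_gap,
    )
    out = []
    for locus in loci:
        locus = assign_family(locus, references.families, min_identity)
        locus = classify_locus(
            locus,
            dict(sequences),
            expected_homeoboxes=references.expected_homeoboxes,
            full_span_states=full_span_states,
        )
        out.append(locus)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_survey(config: RunConfig) -> tuple[dict[str, list[Locus]], PresenceMatrix]:
    """Full survey over the configured genomes; writes GFF3, TSV, matrix, manifest."""
    config.validate()
    if not config.genome_fastas:
        raise PipelineError("survey", "no genome FASTAs configured")
    if config.reference_alignment is None:
        raise PipelineError("survey", "no reference alignment configured")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("build_profile"):
        from .hmm import HomeodomainAlignment

        alignment = HomeodomainAlignment.from_fasta(config.reference_alignment)
        references = ReferenceSet.from_alignment_fasta(config.reference_alignment)
        hmm = build_profile(
            alignment, config.match_occupancy_threshold, config.pseudocount
        )

    locus_tables: dict[str, list[Locus]] = {}
    for species, fasta in sorted(config.genome_fastas.items()):
        with _stage(f"scan:{species}"):
            fasta = Path(fasta)
            if not fasta.exists():
                raise PipelineError(f"scan:{species}", f"missing genome {fasta}")
            sequences = {
                rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")
            }
            loci = survey_genome(
                sequences,
                hmm,
                references,
                species=species,
                bit_threshold=config.bit_threshold,
                min_envelope=config.min_envelope,
                merge_window=config.merge_window,
                full_span_states=config.full_span_states,
                frameshift_gap=config.frameshift_gap,
                min_identity=config.min_identity,
            )
            locus_tables[species] = loci
            write_loci_gff3(loci, out_dir / f"{species}.loci.gff3")
            write_locus_tsv(loci, out_dir / f"{species}.loci.tsv")

    with _stage("matrix"):
        matrix = build_matrix(
            locus_tables,
            families=list(references.families),
            species=sorted(config.genome_fastas),
        )
        write_matrix(matrix, out_dir / "presence_matrix.csv")

    with _stage("manifest"):
        manifest = {
            "homeodyn_version": __version__,
            "parameters": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in vars(config).items()
                if k != "genome_fastas"
            },
            "inputs": {
                "reference_alignment": _sha256(config.reference_alignment),
                **{
                    sp: _sha256(p) for sp, p in sorted(config.genome_fastas.items())
                },
            },
            "outputs": sorted(p.name for p in out_dir.iterdir()),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return locus_tables, matrix


def gainloss_report(
    matrix: PresenceMatrix, tree: SpeciesTree, focal: tuple[str, str]
) -> dict:
    """Dollo events per family plus the per-lineage summary, JSON-ready."""
    events: EventMap = infer_events(matrix, tree)
    summary = lineage_summary(events, tree, focal)
    return {
        "families": {
            fam: {"gain": fe.gain, "losses": sorted(fe.losses)}
            for fam, fe in events.items()
        },
        "lineages": {
            leaf: {
                "gains": s["gains"],
                "losses": s["losses"],
                "n_gains": len(s["gains"]),
                "n_losses": len(s["losses"]),
            }
            for leaf, s in summary.items()
        },
        "focal": list(focal),
    }


def run_table2(
    matrix_path: Path | None = None,
    tree_path: Path | None = None,
    focal: tuple[str, str] = ("human", "mouse"),
    out: Path | None = None,
) -> dict:
    """Gain/loss report for the packaged gene-content table and mammal tree.

    With default arguments this reproduces the headline human-versus-mouse
    lineage comparison from the packaged fixtures.
    """
    with _stage("gainloss"):
        matrix = read_matrix(matrix_path) if matrix_path else table2_matrix()
        tree = parse_tree(Path(tree_path).read_text()) if tree_path else mammal_tree()
        report = gainloss_report(matrix, tree, focal)
    if out is not None:
        Path(out).write_text(json.dumps(report, indent=1))
    return report
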
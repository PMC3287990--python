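"""End-to-end orchestration: detect -> classify -> trim -> census.

``run_pipeline`` executes the full analysis on a FASTA proteome with a
taxonomy sidecar: fold validation of every protein against the globin
template set, domain scanning and architecture classification of the
accepted globins, domain trimming, census aggregation, and (when
alignment ensembles are supplied) overlap scoring and NJ tree building.
Every run writes a manifest recording the configuration, the seed and
SHA-256 digests of all inputs and outputs, so a rerun with the same
inputs and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO

from . import architecture as arch
from . import census as census_mod
from . import fold
from . import msa as msa_mod
from . import phylo
from .simulate import digest
from .templates import GLOBIN_TEMPLATES

logger = logging.getLogger("fungiglobin")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and offending record."""

    def __init__(self, stage: str, record: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on record {record!r}: {cause}")
        self.stage = stage
        self.record = record


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the pipeline, with field defaults.

    The Z threshold of 6.0 (99% probability under the null) and the
    1000 bootstrap replicates are the analysis's standard settings; the
    remaining thresholds parameterize the architecture rule table.
    """

    z_threshold: float = 6.0
    min_hydrophobic_fraction: float = fold.DEFAULT_MIN_HYDROPHOBIC_FRACTION
    n_shuffles: int = fold.DEFAULT_N_SHUFFLES
    sgb_max_length: int = 260
    chimera_cterm_min: int = 100
    n_term_ext_min: int = 25
    normal_fhb_range: Tuple[int, int] = (380, 420)
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("z_threshold", "n_shuffles", "sgb_max_length",
                     "chimera_cterm_min", "n_term_ext_min", "bootstrap_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def classifier_config(self) -> arch.ClassifierConfig:
        return arch.ClassifierConfig(
            sgb_max_length=self.sgb_max_length,
            chimera_cterm_min=self.chimera_cterm_min,
            n_term_ext_min=self.n_term_ext_min,
            normal_fhb_range=self.normal_fhb_range,
        )


def read_fasta(path: Union[str, Path]) -> List[Tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def detect_proteins(
    records: Sequence[Tuple[str, str]],
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Fold-validate every protein; one assessment row per protein."""
    rows = []
    for pid, seq in records:
        try:
            family, template, assessment = fold.assign_family(
                seq,
                GLOBIN_TEMPLATES,
                z_threshold=config.z_threshold,
                min_hydrophobic_fraction=config.min_hydrophobic_fraction,
                n_shuffles=config.n_shuffles,
                seed=config.seed,
            )
            span: Tuple[Optional[int], Optional[int]] = (None, None)
            if family is not None and template is not None:
                pmap, _ = fold.anchor_to_template(seq, template)
                try:
                    span = fold.trim_domain(seq, pmap)
                except fold.TrimmingError:
                    logger.warning("detect: %s accepted but untrimmable", pid)
        except Exception as exc:  # noqa: BLE001 - stage contract
            raise StageError("detect", pid, exc) from exc
        logger.info(
            "detect: %s family=%s z=%s accepted=%s",
            pid, family, None if assessment.z is None else round(assessment.z, 2),
            assessment.accepted,
        )
        rows.append({
            "protein_id": pid,
            "family": family or "",
            "template": template.name if template else "",
            "z": assessment.z,
            "hydrophobic_fraction": assessment.hydrophobic_fraction,
            "f8": assessment.f8_residue or "",
            "accepted": assessment.accepted,
            "span_start": span[0],
            "span_end": span[1],
        })
    return pd.DataFrame(rows)


def classify_proteins(
    records: Sequence[Tuple[str, str]],
    detections: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Scan domains and classify the architecture of every protein."""
    det = detections.set_index("protein_id")
    cconf = config.classifier_config()
    rows = []
    for pid, seq in records:
        try:
            d = det.loc[pid]
            family = d["family"] or None
            if family is not None:
                hits = arch.scan_domains(seq)
            else:
                hits = []
            try:
                call = arch.classify_architecture(
                    hits, family, len(seq), sequence=seq, config=cconf
                )
                label = call.label
                flags = ",".join(call.flags)
                n_term, c_term, signal = call.n_term_ext, call.c_term_ext, call.signal_peptide
            except arch.MultiGlobinError:
                label, flags = "MultiGlobin", "unclassified"
                n_term = c_term = 0
                signal = False
        except Exception as exc:  # noqa: BLE001
            if isinstance(exc, StageError):
                raise
            raise StageError("classify", pid, exc) from exc
        logger.info("classify: %s -> %s", pid, label)
        rows.append({
            "protein_id": pid,
            "species": pid.split("|")[0],
            "label": label,
            "n_term_ext": n_term,
            "c_term_ext": c_term,
            "signal_peptide": signal,
            "length": len(seq),
            "flags": flags,
        })
    return pd.DataFrame(rows)


def trim_proteins(
    records: Sequence[Tuple[str, str]],
    detections: pd.DataFrame,
) -> List[Tuple[str, str]]:
    """Extract the trimmed globin domains of accepted proteins."""
    det = detections.set_index("protein_id")
    out = []
    for pid, seq in records:
        d = det.loc[pid]
        if d["accepted"] and pd.notna(d["span_start"]):
            s, e = int(d["span_start"]), int(d["span_end"])
            out.append((pid, seq[s - 1:e]))
    return out


def _write_fasta(records: Sequence[Tuple[str, str]], path: Path) -> None:
    with path.open("w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def run_pipeline(
    config: PipelineConfig,
    fasta: Union[str, Path],
    taxonomy_tsv: Union[str, Path],
    outdir: Union[str, Path],
    msa_files: Optional[Sequence[Union[str, Path]]] = None,
) -> Dict[str, Path]:
    """Run detect -> classify -> trim -> census (and optionally
    msa-score -> nj) and write all artifacts plus a manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = read_fasta(fasta)
    taxonomy = pd.read_csv(taxonomy_tsv, sep="\t")

    detections = detect_proteins(records, config)
    det_path = outdir / "detections.tsv"
    detections.to_csv(det_path, sep="\t", index=False)

    calls = classify_proteins(records, detections, config)
    calls_path = outdir / "architecture_calls.tsv"
    calls.to_csv(calls_path, sep="\t", index=False)

    trimmed = trim_proteins(records, detections)
    trim_path = outdir / "trimmed_domains.fasta"
    _write_fasta(trimmed, trim_path)

    table = census_mod.census_from_calls(calls, taxonomy)
    census_path = outdir / "census.tsv"
    table.to_csv(census_path, sep="\t", index=False)
    summary = census_mod.summarize(table, group_by="phylum")
    summary_path = outdir / "census_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)

    artifacts = {
        "detections": det_path,
        "architecture_calls": calls_path,
        "trimmed_domains": trim_path,
        "census": census_path,
        "census_summary": summary_path,
    }

    if msa_files:
        ensemble = [msa_mod.MSA.from_file(p) for p in msa_files]
        names = [Path(p).name for p in msa_files]
        if len(ensemble) > 1:
            winner, scores = msa_mod.select_best(ensemble, names)
            score_path = outdir / "msa_scores.tsv"
            pd.DataFrame(
                {"alignment": scores.names, "mean_overlap": scores.means}
            ).to_csv(score_path, sep="\t", index=False)
            artifacts["msa_scores"] = score_path
        else:
            winner = ensemble[0]
        if len(winner.ids) >= 3:
            tree, _ = phylo.bootstrap(
                winner, n_reps=config.bootstrap_reps, seed=config.seed
            )
            tree_path = outdir / "nj_tree.nwk"
            phylo.write_newick(tree, tree_path)
            artifacts["nj_tree"] = tree_path
        else:
            logger.warning("nj: skipped, winning alignment has < 3 sequences")

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "inputs": {
            "fasta": digest(Path(fasta).read_bytes()),
            "taxonomy": digest(Path(taxonomy_tsv).read_bytes()),
        },
        "outputs": {k: digest(p.read_bytes()) for k, p in sorted(artifacts.items())},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = manifest_path
    return artifacts
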
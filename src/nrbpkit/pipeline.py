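"""End-to-end orchestration: filter -> classify -> divergence.

The pipeline mirrors the order of the underlying analysis: candidate homologs
are filtered by the reciprocal-search chain, the accepted sequences are
classified as pseudokinases by the catalytic-triad rule, and an externally
inferred phylogeny is consumed for the clade divergence statistics.  Each
stage writes its outputs before the next starts, so a failure leaves the
completed stages' results intact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ortholog, phylo, triad

logger = logging.getLogger("nrbpkit")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run (echoed into the report)."""

    outdir: str
    forward_hits: str | None = None
    reverse_hits: str | None = None
    sequences: str | None = None  # FASTA of candidate sequences
    profile_seed: str | None = None  # aligned FASTA
    triad_columns: str | None = None  # sidecar TSV: name <TAB> 0-based column
    tree: str | None = None  # Newick
    clades: str | None = None  # TSV leaf <TAB> clade
    clade_pairs: list[list[str]] = field(default_factory=list)
    outgroup: str | None = None
    filter: dict = field(default_factory=dict)  # FilterConfig fields
    reference_lengths: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = json.load(fh)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _read_triad_columns(path: str | Path) -> tuple[int, int, int]:
    cols: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, idx = line.split("\t")
            cols[name] = int(idx)
    try:
        return (cols["beta3_K"], cols["HRD_D"], cols["DFG_D"])
    except KeyError as exc:
        raise ValueError(f"triad column file {path} is missing {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns (and writes) the machine-readable report."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
    }

    accepted: set[str] | None = None
    if config.forward_hits and config.reverse_hits:
        stage = "filter"
        try:
            with open(config.forward_hits) as fh:
                forward = ortholog.parse_hit_table(fh)
            with open(config.reverse_hits) as fh:
                reverse = ortholog.parse_hit_table(fh)
            fcfg_fields = dict(config.filter)
            if "folded_region" in fcfg_fields and fcfg_fields["folded_region"] is not None:
                fcfg_fields["folded_region"] = tuple(fcfg_fields["folded_region"])
            if "accepted_reference_ids" in fcfg_fields:
                fcfg_fields["accepted_reference_ids"] = frozenset(
                    fcfg_fields["accepted_reference_ids"]
                )
            fcfg = ortholog.FilterConfig(**fcfg_fields)
            accepted, table = ortholog.filter_candidates(
                forward, reverse, config.reference_lengths, fcfg
            )
            table.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
            (outdir / "accepted_ids.txt").write_text(
                "".join(f"{c}\n" for c in sorted(accepted))
            )
            report["stages"][stage] = {
                "candidates_in": int(table.shape[0]),
                "accepted": len(accepted),
            }
            logger.info("filter: %d/%d candidates accepted", len(accepted), table.shape[0])
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if config.sequences and config.profile_seed and config.triad_columns:
        stage = "classify"
        try:
            records = _read_fasta(config.sequences)
            if accepted is not None:
                records = [r for r in records if r[0] in accepted]
            seed_aln = _read_fasta(config.profile_seed)
            spec = _read_triad_columns(config.triad_columns)
            if not records:
                logger.warning("classify: 0 sequences after filtering")
                report["stages"][stage] = {"sequences": 0, "pseudokinases": 0}
            else:
                profile = triad.build_profile(seed_aln, spec)
                calls = triad.classify_sequences(records, profile)
                rows = [
                    {
                        "id": c.sequence_id,
                        "residue_beta3": c.residues["beta3_K"],
                        "residue_HRD": c.residues["HRD_D"],
                        "residue_DFG": c.residues["DFG_D"],
                        "n_mismatches": c.n_mismatches,
                        "is_pseudokinase": c.is_pseudokinase,
                    }
                    for c in calls
                ]
                pd.DataFrame(rows).to_csv(outdir / "triad_calls.tsv", sep="\t", index=False)
                n_pk = sum(c.is_pseudokinase for c in calls)
                report["stages"][stage] = {
                    "sequences": len(calls),
                    "pseudokinases": int(n_pk),
                    "pseudokinase_fraction": n_pk / len(calls),
                }
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if config.tree and config.clades:
        stage = "divergence"
        try:
            tree = phylo.parse_newick(Path(config.tree).read_text())
            if config.outgroup:
                tree = phylo.root_at_outgroup(tree, config.outgroup)
            distances = phylo.leaf_root_distances(tree)
            assignment: dict[str, str] = {}
            with open(config.clades) as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line or line.startswith("#"):
                        continue
                    leaf, clade = line.split("\t")
                    assignment[leaf] = clade
            pairs = [tuple(p) for p in config.clade_pairs]
            if pairs:
                rep = phylo.compare_clade_distances(distances, assignment, pairs)
                rep.tests.to_csv(outdir / "divergence_tests.tsv", sep="\t", index=False)
                rep.clade_stats.to_csv(outdir / "clade_stats.tsv", sep="\t", index=False)
                report["stages"][stage] = {
                    "n_leaves": len(distances),
                    "pairs_tested": len(pairs),
                    "clade_means": {
                        r["clade"]: r["mean"] for r in rep.clade_stats.to_dict("records")
                    },
                }
            else:
                logger.warning("divergence: no clade pairs configured; skipped tests")
                report["stages"][stage] = {"n_leaves": len(distances), "pairs_tested": 0}
            pd.DataFrame(
                sorted(distances.items()), columns=["leaf", "distance"]
            ).to_csv(outdir / "leaf_root_distances.tsv", sep="\t", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
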
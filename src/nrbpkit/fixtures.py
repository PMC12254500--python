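"""Loaders for the packaged text fixtures.

Two fixtures ship with the package:

* a 10-candidate toy filter table pair with hand-chosen E-values, reverse
  hits and alignment spans, each candidate exercising one rule of the
  acceptance chain (documented in ``data/toy_filter/expected.tsv``), and
* a small *synthetic* kinase-domain seed alignment with annotated triad
  columns (``data/kinase_seed_synthetic.afa``), generated by the package's
  own family simulator — a desk-scale stand-in for a curated kinase-domain
  seed such as Pfam PF00069, shipped so the classifier is usable and testable
  offline.  Real seed alignments can be used through the same interfaces.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd

from .ortholog import FilterConfig, HitRecord, parse_hit_table

_DATA = files("nrbpkit") / "data"

TOY_REFERENCE_LENGTHS = {"REF1": 500}
TOY_FILTER_CONFIG = dict(
    evalue_cutoff=1e-28,
    min_reference_coverage=0.80,
    folded_region=(44, 480),
    folded_tolerance=40,
    accepted_reference_ids=frozenset({"REF1"}),
)


def toy_filter_tables() -> tuple[list[HitRecord], list[HitRecord], pd.DataFrame, FilterConfig, dict[str, int]]:
    """The packaged 10-candidate filter fixture.

    Returns (forward hits, reverse hits, expected per-rule table, filter
    config, reference lengths).
    """
    forward = parse_hit_table((_DATA / "toy_filter" / "forward_hits.tsv").read_text().splitlines())
    reverse = parse_hit_table((_DATA / "toy_filter" / "reverse_hits.tsv").read_text().splitlines())
    expected_lines = [
        line for line in (_DATA / "toy_filter" / "expected.tsv").read_text().splitlines()
        if line and not line.startswith("#")
    ]
    rows = []
    for line in expected_lines:
        fields = line.split("\t")
        rows.append(
            {
                "candidate": fields[0],
                "pass_evalue": fields[1] == "True",
                "pass_reciprocal": fields[2] == "True",
                "pass_coverage": fields[3] == "True",
                "pass_folded_region": fields[4] == "True",
                "accepted": fields[5] == "True",
            }
        )
    expected = pd.DataFrame(rows)
    return forward, reverse, expected, FilterConfig(**TOY_FILTER_CONFIG), dict(TOY_REFERENCE_LENGTHS)


def kinase_seed() -> tuple[list[tuple[str, str]], tuple[int, int, int]]:
    """The synthetic kinase-domain seed alignment and its triad columns."""
    records: list[tuple[str, str]] = []
    label = None
    chunks: list[str] = []
    for line in (_DATA / "kinase_seed_synthetic.afa").read_text().splitlines():
        if line.startswith(">"):
            if label is not None:
                records.append((label, "".join(chunks)))
            label = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if label is not None:
        records.append((label, "".join(chunks)))

    cols: dict[str, int] = {}
    for line in (_DATA / "kinase_seed_synthetic_triad.tsv").read_text().splitlines():
        if line and not line.startswith("#"):
            name, idx = line.split("\t")
            cols[name] = int(idx)
    return records, (cols["beta3_K"], cols["HRD_D"], cols["DFG_D"])


def reference_pair_paths() -> tuple[Path, Path] | None:
    """Paths of the real NRBP1/NRBP2 FASTA files, if the user installed them.

    The canonical human sequences are not redistributed (see
    ``data/reference/README.txt``); returns ``None`` when absent.
    """
    ref_dir = Path(str(_DATA / "reference"))
    p1 = ref_dir / "NRBP1_HUMAN.fasta"
    p2 = ref_dir / "NRBP2_HUMAN.fasta"
    if p1.exists() and p2.exists():
        return p1, p2
    return None
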
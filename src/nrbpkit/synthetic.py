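"""Synthetic gene families, trees and quantification tables with known truth.

The family generator emulates the statistical structure the analysis assumes
for the NRBP paralog family: a single-copy "invertebrate" clade, and two
post-duplication paralog clades (P1, NRBP1-like; P2, NRBP2-like) in which the
P2 clade evolves at an elevated substitution rate ρ and clades can be planted
with intact (K/D/D) or degenerate catalytic triads.

Design of the tree noise: every clade has a balanced (symmetric-split)
topology of fixed depth; internal and stem edges have *fixed* length
(``base_rate`` expected substitutions per site per edge) and only the pendant
edges are random (exponential with mean ``base_rate``).  Leaf-to-root
distances are therefore i.i.d. within a clade, which is what the downstream
leaf-level Welch test assumes; edges of the P2 subtree, including its stem,
are scaled by ρ.  With ρ = 1 the two paralog clades are exchangeable in
distribution.

Sequences evolve by i.i.d. per-site replacement with probability
1 − exp(−branch length), uniform over the other 19 residues; no indels, no
empirical substitution matrix.  The three triad columns are held invariant so
triad state stays a controlled variable.

Everything is driven by a single integer seed expanded into independent
streams (tree, sequences, triad planting), so identical configurations give
byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .ortholog import HitRecord, ScoringConfig, local_search
from .quant import CT_COLUMNS
from .triad import AA, TRIAD_CONSENSUS, TRIAD_NAMES

CLADES = ("invertebrate", "P1", "P2")
FAST_CLADE = "P2"

__all__ = [
    "FamilySimConfig",
    "SimOutput",
    "simulate_family",
    "simulate_ct_table",
    "simulate_hit_tables",
    "write_sim_output",
]

_AA_INDEX = {a: i for i, a in enumerate(AA)}


@dataclass
class FamilySimConfig:
    """Parameters of the three-clade family simulation."""

    n_leaves_per_clade: int = 50
    seq_length: int = 300
    base_rate: float = 0.05
    rate_multiplier_fast_clade: float = 2.0
    triad_state_per_clade: dict[str, str] = field(
        default_factory=lambda: {c: "degenerate" for c in CLADES}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves_per_clade <= 0:
            raise ValueError("n_leaves_per_clade must be positive")
        if self.seq_length < 16:
            raise ValueError("seq_length must be at least 16 residues")
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if self.rate_multiplier_fast_clade < 0:
            raise ValueError("rate_multiplier_fast_clade must be >= 0")
        for clade in CLADES:
            state = self.triad_state_per_clade.get(clade)
            if state not in ("intact", "degenerate"):
                raise ValueError(
                    f"triad_state_per_clade[{clade!r}] must be 'intact' or 'degenerate'"
                )


@dataclass
class SimOutput:
    """Simulated family with its ground truth."""

    sequences: list[tuple[str, str]]
    true_tree: dendropy.Tree
    true_labels: dict[str, str]
    true_triad_states: dict[str, str]
    triad_positions: tuple[int, int, int]  # 0-based residue indices
    config: FamilySimConfig

    @property
    def newick(self) -> str:
        return self.true_tree.as_string(schema="newick").strip()


def _balanced_split(labels: list[str]) -> dict:
    """Symmetric birth topology: recursively halve the leaf list."""
    if len(labels) == 1:
        return {"leaf": labels[0]}
    mid = (len(labels) + 1) // 2
    return {"children": (_balanced_split(labels[:mid]), _balanced_split(labels[mid:]))}


def _build_clade(
    taxon_ns, topo: dict, scale: float, base: float, rng: np.random.Generator
):
    node = dendropy.Node()
    if "leaf" in topo:
        node.taxon = taxon_ns.require_taxon(label=topo["leaf"])
        node.edge.length = float(rng.exponential(base) * scale)
    else:
        node.edge.length = base * scale
        for child_topo in topo["children"]:
            node.add_child(_build_clade(taxon_ns, child_topo, scale, base, rng))
    return node


def simulate_family(config: FamilySimConfig) -> SimOutput:
    """Simulate the three-clade family: tree, sequences and planted triads."""
    ss = np.random.SeedSequence(config.seed)
    rng_tree, rng_seq, rng_triad = (np.random.default_rng(s) for s in ss.spawn(3))

    n = config.n_leaves_per_clade
    base = config.base_rate
    rho = config.rate_multiplier_fast_clade

    labels = {
        clade: [f"{clade}_{i + 1:04d}" for i in range(n)] for clade in CLADES
    }

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True
    root = tree.seed_node

    clade_roots = {}
    # pendant-edge randomness is drawn clade by clade in a fixed order
    for clade in CLADES:
        scale = rho if clade == FAST_CLADE else 1.0
        topo = _balanced_split(labels[clade])
        clade_root = _build_clade(taxon_ns, topo, scale, base, rng_tree)
        # stem edge of the clade (fixed length, scaled for the fast clade)
        clade_root.edge.length = base * scale
        clade_roots[clade] = clade_root

    inner = dendropy.Node()
    inner.edge.length = base
    inner.add_child(clade_roots["P1"])
    inner.add_child(clade_roots["P2"])
    root.add_child(clade_roots["invertebrate"])
    root.add_child(inner)

    # triad residue positions: three interior, well-separated sites
    L = config.seq_length
    triad_positions = (L // 4, L // 2, (3 * L) // 4)

    # planted residues per clade
    planted: dict[str, tuple[str, str, str]] = {}
    consensus = tuple(TRIAD_CONSENSUS[name] for name in TRIAD_NAMES)
    for clade in CLADES:
        if config.triad_state_per_clade[clade] == "intact":
            planted[clade] = consensus
        else:
            residues = []
            for cons in consensus:
                choices = [a for a in AA if a != cons]
                residues.append(choices[int(rng_triad.integers(len(choices)))])
            planted[clade] = tuple(residues)

    # evolve sequences (integer-coded) down the tree
    root_seq = rng_seq.integers(0, 20, size=L)
    triad_idx = np.array(triad_positions)
    root_seq[triad_idx] = [_AA_INDEX[c] for c in consensus]
    free = np.ones(L, dtype=bool)
    free[triad_idx] = False

    def mutate(seq: np.ndarray, branch: float) -> np.ndarray:
        out = seq.copy()
        p = 1.0 - np.exp(-branch)
        hit = (rng_seq.random(L) < p) & free
        k = int(hit.sum())
        if k:
            out[hit] = (out[hit] + rng_seq.integers(1, 20, size=k)) % 20
        return out

    sequences: dict[str, np.ndarray] = {}

    def walk(node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            child_seq = mutate(seq, child.edge.length)
            if child.is_leaf():
                sequences[child.taxon.label] = child_seq
            else:
                walk(child, child_seq)

    # the invertebrate clade descends straight from the root; the paralog
    # clades descend from the duplication node one (fixed) edge below it
    inner_seq = mutate(root_seq, inner.edge.length)
    for clade, parent_seq in (
        ("invertebrate", root_seq), ("P1", inner_seq), ("P2", inner_seq)
    ):
        clade_root = clade_roots[clade]
        seq = mutate(parent_seq, clade_root.edge.length)
        seq[triad_idx] = [_AA_INDEX[c] for c in planted[clade]]
        if clade_root.is_leaf():
            sequences[clade_root.taxon.label] = seq
        else:
            walk(clade_root, seq)

    records = []
    true_labels: dict[str, str] = {}
    true_states: dict[str, str] = {}
    for clade in CLADES:
        for label in labels[clade]:
            aa_seq = "".join(AA[i] for i in sequences[label])
            records.append((label, aa_seq))
            true_labels[label] = clade
            true_states[label] = config.triad_state_per_clade[clade]

    return SimOutput(
        sequences=records,
        true_tree=tree,
        true_labels=true_labels,
        true_triad_states=true_states,
        triad_positions=triad_positions,
        config=config,
    )


def plant_insertions(
    records: list[tuple[str, str]],
    rng: np.random.Generator,
    max_length: int = 10,
) -> list[tuple[str, str]]:
    """Insert 1..max_length random residues at a random position of each sequence.

    Used to exercise profile alignment: the simulator itself is indel-free,
    so insertions are planted afterwards.  Positions and contents are drawn
    from ``rng``; triad residues themselves are never altered (the insertion
    goes between existing residues).
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    out = []
    for label, seq in records:
        k = int(rng.integers(1, max_length + 1))
        pos = int(rng.integers(0, len(seq) + 1))
        insert = "".join(AA[i] for i in rng.integers(0, 20, size=k))
        out.append((label, seq[:pos] + insert + seq[pos:]))
    return out


def simulate_ct_table(
    true_fold: float,
    dilution_factor: float = 10.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    *,
    target: str = "L1",
    control_rip_ct: float = 26.0,
    input_ct: float = 20.0,
) -> pd.DataFrame:
    """Ct table constructed so the RIP enrichment formula recovers ``true_fold``.

    With ``noise_sd = 0`` the estimator returns ``true_fold`` exactly; with
    noise, independent Gaussian Ct noise of that standard deviation is added
    to every measurement.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be positive")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    exp_rip_ct = control_rip_ct - np.log2(true_fold)

    rows = []
    for group, rip_ct in (("experimental", exp_rip_ct), ("control", control_rip_ct)):
        for rep in range(1, n_replicates + 1):
            sample = f"{group}_{rep}"
            for fraction, ct in (("RIP", rip_ct), ("input", input_ct)):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "fraction": fraction,
                        "target": target,
                        "ct": ct + noise,
                        "dilution_factor": dilution_factor if fraction == "input" else np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=list(CT_COLUMNS))


def simulate_hit_tables(
    sim: SimOutput,
    references: list[tuple[str, str]],
    scoring: ScoringConfig | None = None,
) -> tuple[list[HitRecord], list[HitRecord]]:
    """Desk-scale search of the simulated family against reference sequences.

    Forward table: each simulated sequence as query against every reference;
    reverse table: each reference as query against every simulated sequence.
    Empty sequences are skipped with a warning.  Hits beyond the scoring
    config's E-value ceiling are omitted.
    """
    if not references:
        raise ValueError("references must be non-empty")
    scoring = scoring or ScoringConfig()

    def search_all(queries, subjects):
        hits: list[HitRecord] = []
        for q_id, q_seq in queries:
            if not q_seq:
                warnings.warn(f"skipping empty sequence {q_id!r}")
                continue
            for s_id, s_seq in subjects:
                if not s_seq:
                    warnings.warn(f"skipping empty sequence {s_id!r}")
                    continue
                hit = local_search(q_seq, s_seq, scoring, query_id=q_id, subject_id=s_id)
                if hit is not None:
                    hits.append(hit)
        return hits

    forward = search_all(sim.sequences, references)
    reverse = search_all(references, sim.sequences)
    return forward, reverse


def write_sim_output(sim: SimOutput, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, Newick and ground-truth TSVs for a simulated family."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "family.fasta",
        "tree": outdir / "true_tree.nwk",
        "clades": outdir / "true_clades.tsv",
        "triads": outdir / "true_triad_states.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for label, seq in sim.sequences:
            fh.write(f">{label}\n{seq}\n")
    with open(paths["tree"], "w") as fh:
        fh.write(sim.newick + "\n")
    with open(paths["clades"], "w") as fh:
        for label, clade in sim.true_labels.items():
            fh.write(f"{label}\t{clade}\n")
    with open(paths["triads"], "w") as fh:
        for label, state in sim.true_triad_states.items():
            fh.write(f"{label}\t{state}\n")
    return paths
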
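# nrbpkit

Tools for the computational analysis of the NRBP pseudokinase family — the
vertebrate paralogs NRBP1 and NRBP2 and their single-copy invertebrate
ancestors — packaged as a tested, reusable pipeline:

* **Ortholog filtering** (`nrbpkit.ortholog`): candidate homologs from
  pairwise protein searches are accepted through a four-rule chain — forward
  E-value ≤ 1e-28 (inclusive), reciprocal top-hit against the human proteome
  must be NRBP1 or NRBP2, union-of-HSPs coverage of the reference ≥ 80%, and
  at most 40 residues of the reference's predicted folded region left
  uncovered.
* **Pseudokinase classification** (`nrbpkit.triad`): each protein is aligned
  to a kinase-domain position-specific scoring model and the three catalytic
  triad residues are read — the β3-strand ATP-binding lysine (VAIK), the
  catalytic aspartate of the HRDxxxN loop, and the metal-binding aspartate of
  the DFG motif.  A protein with ≥ 2 of the 3 consensus residues (K/D/D)
  missing is rated a pseudokinase.
* **Alignment masking and identity** (`nrbpkit.msa`): columns with gaps in
  ≥ 10% of sequences are removed before tree inference; percent identity
  comes from global affine-gap (Needleman–Wunsch) alignment.
* **Divergence statistics** (`nrbpkit.phylo`): leaf-to-root branch-length
  distances d(leaf) = Σ branch lengths on the root path (substitutions per
  site), clade monophyly/support checks, two-sided Welch's t-tests
  t = (x̄₁−x̄₂)/√(s₁²/n₁+s₂²/n₂) with Welch–Satterthwaite degrees of freedom
  and Benjamini–Hochberg correction across clade pairs, and a two-sided
  paired t-test for per-sequence bit-score comparisons.
* **Quantification** (`nrbpkit.quant`): RIP-qPCR fold enrichment
  ΔCt = Ct(RIP) − [Ct(Input) − log₂(input dilution factor)],
  ΔΔCt = ΔCt(experimental) − ΔCt(control), fold = 2^(−ΔΔCt), optionally
  adjusted by the ORF1p IP-efficiency ratio; relative expression by
  2^(−ΔΔCt); and relative L1 retrotransposition activity as the colony-count
  ratio L1-neo / empty-vector.
* **Synthetic data** (`nrbpkit.synthetic`): a generator producing gene
  families with a known tree, planted triad states, and an elevated
  substitution rate ρ in the NRBP2-like clade, plus Ct tables and hit tables
  with known ground truth, so every stage of the pipeline is verifiable
  offline.

## Worked example

Simulate a family under study-like conditions (50 leaves per clade, 300
residues, base rate 0.05 substitutions/site per edge, NRBP2-like clade
evolving twice as fast, all clades carrying degenerate triads), classify
every sequence, and compare clade divergences:

```python
from nrbpkit.synthetic import FamilySimConfig, simulate_family
from nrbpkit.triad import build_profile, classify_sequences
from nrbpkit.phylo import leaf_root_distances, compare_clade_distances

config = FamilySimConfig(
    n_leaves_per_clade=50, seq_length=300, base_rate=0.05,
    rate_multiplier_fast_clade=2.0, seed=1,
    triad_state_per_clade={"invertebrate": "degenerate",
                           "P1": "degenerate", "P2": "degenerate"},
)
sim = simulate_family(config)

profile = build_profile(
    [r for r in sim.sequences if r[0].startswith("P1")], sim.triad_positions
)
calls = classify_sequences(sim.sequences, profile)
print(f"pseudokinases: {sum(c.is_pseudokinase for c in calls)}/{len(calls)}")

distances = leaf_root_distances(sim.true_tree)
report = compare_clade_distances(
    distances, sim.true_labels,
    [("P2", "P1"), ("P2", "invertebrate"), ("P1", "invertebrate")],
)
print(report.clade_stats.to_string(index=False))
print(report.tests[["clade_a", "clade_b", "t", "df", "p_adjusted"]].to_string(index=False))
```

This prints:

```
pseudokinases: 150/150
       clade  n     mean       sd
          P1 50 0.390058 0.065179
          P2 50 0.717450 0.099075
invertebrate 50 0.338890 0.069599
clade_a      clade_b         t        df   p_adjusted
     P2           P1 19.520669 84.722900 6.311919e-33
     P2 invertebrate 22.108234 87.890646 3.454759e-37
     P1 invertebrate  3.794455 97.581149 2.567757e-04
```

Every sequence is called a pseudokinase (all triads were planted
degenerate), and the NRBP2-like clade's mean leaf-to-root distance (0.72
substitutions/site) significantly exceeds both the NRBP1-like clade's (0.39)
and the invertebrate clade's (0.34) after BH correction — the fast clade's
doubled rate is recovered.  The small but significant P1-vs-invertebrate
difference reflects the extra post-duplication edge on the paralog clades'
root paths.

The same stages are available from the shell via the `nrbpkit` command
(`simulate`, `filter`, `classify`, `mask`, `identity`, `divergence`, `rip`,
`ddct`, `retro`, `run`); `nrbpkit run --config config.json` executes
filter → classify → divergence end to end and writes a JSON run report.

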
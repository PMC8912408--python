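# plastshift

Comparative structural analysis of plastid genomes (plastomes), built
for the kind of study where a handful of newly assembled chloroplast
genomes is compared against relatives: where are the inverted-repeat
boundaries, which genes did they capture or release, which spacers
carry insertions, which short segments flipped orientation, and how
much phylogenetic signal the resulting supermatrix carries.

## What it does

A typical angiosperm plastome is a circle with a quadripartite layout:
a large and a small single-copy region (LSC, SSC) separated by two
identical inverted repeats (IRa, IRb). The four junctions are named
J_LB (LSC/IRb), J_SB (IRb/SSC), J_SA (SSC/IRa) and J_LA (IRa/LSC);
their movement ("ebb and flow" of the IR) duplicates or releases genes
and is a workhorse character in plastome comparative genomics.

The package covers, as library functions and a `plastshift` CLI:

- **Quadripartite detection** — the IR pair is found as the maximal
  pair of disjoint, exactly reverse-complementary substrings on the
  circle (seed-and-extend on the doubled sequence; exact, rotation- and
  strand-invariant), then the genome is rotated to a canonical
  LSC→IRb→SSC→IRa orientation. Region lengths, GC content and a gene
  census (proteins with pseudogene counts, tRNAs, rRNAs) come out in
  the familiar per-genome table format.
- **Junction typing** — each junction is located relative to the
  annotation and classified `within:<gene>`, `within-intron:<gene>` or
  `between:<geneA>,<geneB>`, with overlap extents into the IR and the
  list of LSC-origin payload genes (trnH, psbA copies) captured inside
  the repeat.
- **Spacer-insertion screening** — a named intergenic spacer (e.g.
  trnV(GAC)–rrn16) is measured against a baseline length or reference
  panel; insertions are called above a minimum excess and payload
  pseudogene fragments (psbA, trnH, trnV) are recovered by local
  alignment with explicit identity/length/score floors.
- **In-silico PCR** — primer sites on both strands of the circle with
  a mismatch budget and a strict 3′ anchor; convergent site pairs
  within a product-size cap become amplicons. Divergently oriented
  sites yield no product, which is exactly the logic a junction-state
  survey with one primer pair exploits.
- **Junction coverage QC** — median read depth in windows flanking
  each junction versus a small window centered on it; a localized dip
  flags a junction whose assembly deserves re-inspection.
- **Small inversions** — alignment blocks carried by a minority of taxa
  in reverse-complement orientation (typically 3–62 bp, bounded by
  complementary hairpin arms) are detected against the column-majority
  consensus and can be re-oriented in place to restore positional
  homology before phylogenetic analysis; a genome-level variant detects
  larger inversions (e.g. a tRNA-cluster flip) between two genomes.
- **Supermatrix statistics** — gap-rich column masking, block
  concatenation with a partition table, constant/singleton/
  parsimony-informative site classification, Fitch parsimony length
  with consistency index CI = Σmᵢ/Σsᵢ and homoplasy index HI = 1 − CI,
  per-branch site concordance factors (sCF/sDF1/sDF2 over sampled
  quartets) and strict-bipartition synapomorphy counts.
- **Synthetic data** — a generator that emits annotated quadripartite
  GenBank records with configurable region lengths, junction-shift
  events, planted insertions and inversions, plus tree-based alignment
  simulation (Jukes–Cantor) and overdispersed depth profiles — all with
  machine-checkable ground truth, so the whole pipeline is testable
  without downloading anything.

## Worked example

```python
from plastshift import (detect_inverted_repeat, locate_junctions,
                        classify_junction, screen_spacer_insertion)
from plastshift.synthetic import (SyntheticPlastomeSpec, StructuralEvent,
                                  generate_plastome, payload_library)

spec = SyntheticPlastomeSpec(seed=11, events=[
    StructuralEvent("jla_shift_with_insertion",
                    {"spacer": ("trnV-GAC", "rrn16"), "length": 1100,
                     "payload_genes": ["psbA-fragment", "trnH"]})])
genome, truth = generate_plastome(spec)

part = detect_inverted_repeat(genome)
print(part.lsc_length, part.ssc_length, part.ir_length)
# 90000 17000 19100        <- the J_LA shift grew each IR copy by 1100 bp

profile = locate_junctions(genome, part)
print(classify_junction(profile, "J_LB").payload_genes)
# ['psbA', 'trnH-GTG', 'trnH-GTG', 'psbA']   <- captured copies, both IRs

report = screen_spacer_insertion(
    genome, ("trnV-GAC", "rrn16"), payload_library(spec),
    baseline=truth.insertions[0].baseline_spacer_length)
print(report.insertion_length,
      [(f.gene, f.matched_length, f.identity)
       for f in report.embedded_fragments])
# 1100 [('psbA', 350, 100.0), ('trnH', 75, 100.0)]
```

The same analyses are available from the shell, one subcommand per
procedure: `regions`, `junctions`, `screen`, `pcr`, `depthqc`,
`inversions`, `flankir`, `matrix build|stats`, `scf`, `synth
genome|alignment|depth`, `report`. For example:

```bash
plastshift synth genome --seed 7 --out out/
plastshift regions out/synthetic.gb --json
plastshift junctions out/synthetic.gb
```

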
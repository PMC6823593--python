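# rmnet — rule-based microbial network inference

`rmnet` infers directed, signed ecological interaction networks among
bacterial taxa (OTUs, genera, or sub-OTU oligotypes) from multi-sample
relative-abundance tables, as produced by standard amplicon pipelines.  It
is aimed at microbial ecologists who already have mothur `.relabund` /
`.shared` tables or oligotyping `matrix_percents.txt` files and want to go
beyond pairwise co-occurrence: the rule-based approach proposes, for every
ordered triplet of taxa, the hypothesis *"target X is promoted by cooperator
C and impeded by competitor K"* and keeps only the hypotheses the data never
contradict.

The package also ships the supporting steps needed to run the analysis
end-to-end without external tools: Shannon-entropy oligotyping of aligned
amplicon reads, mothur-convention alpha-diversity estimators with
rarefaction, deterministic network export/rendering, and a synthetic
community generator with planted interactions for benchmarking.

## The rule model

Abundance changes between sample pairs are discretized with a steady band
of half-width ε: UP if Δ > ε, DOWN if Δ < −ε, else STEADY.  For a triplet
(X; C; K), a sample pair is *predictive* when the regulators move in
opposite directions:

    C UP,  K DOWN  ⇒  predict X UP
    C DOWN, K UP   ⇒  predict X DOWN

Each predictive pair supports the triplet if X moves as predicted and
contradicts it otherwise (a STEADY X on a predictive pair counts as a
contradiction).  The conformity score is

    s = (support − contradiction) / (support + contradiction)

and a triplet is accepted when it has at least `m_min` predictive pairs and
s ≥ `s_min` (defaults: `m_min = 3`, `s_min = 1.0`, i.e. zero
contradictions).  Every accepted triplet contributes the directed edges
C→X (cooperative) and K→X (competitive); duplicates merge keeping the
maximum score.  By construction no node receives a cooperative edge without
also receiving a competitive one — the algorithm must name both a promoter
and an impeder for any target it reports.

Taxa enter the analysis only if their relative abundance reaches 0.1%
(`theta_min = 0.001`) in at least one sample, and with two-region metadata
each node is categorized as present at both sites or at one site only.

## Worked example

A three-taxon toy in mothur `.relabund` dialect, where X tracks Y and
anti-tracks Z across four samples:

```
label	Group	numOtus	X	Y	Z
0.03	s1	3	0.10	0.10	0.20
0.03	s2	3	0.30	0.20	0.05
0.03	s3	3	0.05	0.05	0.25
0.03	s4	3	0.33	0.25	0.10
```

```
rmnet infer --input toy.relabund --epsilon 0.01 --pairs consecutive --out toy
```

prints `network: 3 nodes, 4 edges, 2 accepted triplets` and writes
`toy.edgelist.tsv`:

```
source	target	sign	weight	n_triplets
X	Y	cooperative	1.000000	1
Y	X	cooperative	1.000000	1
Z	X	competitive	1.000000	1
Z	Y	competitive	1.000000	1
```

Reading `toy.triplets.tsv`: of the six ordered triplets, (X; Y; Z) and
(Y; X; Z) are supported on all three consecutive sample pairs (score 1.0,
accepted); swapping cooperator and competitor gives score −1.0 (perfect
anti-conformity, rejected); and Z as target is never predictive because its
putative regulators X and Y co-move.  The network therefore contains mutual
cooperation between X and Y, with Z competing against both — and no mutual
negative pair, as `rmnet.network_summary` reports
(`{'n_nodes': 3, 'n_coop_edges': 2, 'n_comp_edges': 2, 'n_mutual_negative': 0}`).

The other subcommands follow the same shape, e.g.

```
rmnet oligotype --fasta aligned.fasta --components 2 --out matrix_percents.txt
rmnet diversity --shared counts.shared --subsample 0 --seed 1 --out alpha.tsv
rmnet simulate  --spec spec.yaml --seed 7 --out sim.relabund --truth truth.tsv
rmnet render    --network toy.graphml --seed 7 --out toy.png
```

For a uniform sample of 10 taxa × 100 reads each, `rmnet diversity` reports
Shannon H = 2.302585 (= ln 10), evenness 1.0, Good's coverage 1.0 and
unbiased inverse Simpson 10.0909 — the textbook closed forms.

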
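# chromnet

Analysis of 3D chromatin interaction networks for regulatory genomics.

Chromatin-conformation assays (ChIA-PET, HiChIP, Hi-C) yield pairwise contacts
between genomic loci. Representing open-chromatin peaks as nodes and contacts
as edges turns a cell's regulatory landscape into a graph, whose *connectivity
patterns* carry information that individual contacts do not: cell-type-specific
regulatory elements — broad H3K4me3 domains at promoters and super enhancers —
occupy distinctive network positions. `chromnet` implements the full analysis
as a tested, reusable pipeline:

- **Loop calling** — significant interactions from valid read pairs
  (hypergeometric test over peak pairs, BH-corrected) or from a binned contact
  matrix (four HiCCUPS-style local-background filters — donut, vertical,
  horizontal, lower-left — each Poisson-tested and BH-corrected; a contact must
  pass all four).
- **Network construction** — nodes are DNase I hypersensitive sites; a call
  becomes an edge only if both anchors overlap a peak; inter-chromosomal edges
  and spans > 1 Mb are removed; duplicate calls merge with PET counts summed.
- **Annotation** — one regulatory label per node from a ChromHMM-style
  segmentation under a fixed priority schema (enhancer/promoter > insulator >
  poised promoter > repressed > transcribed > low signal, with a 2 kb TSS rule
  breaking promoter/enhancer ties), then broad-domain and super-enhancer
  overlays from region calls.
- **Interaction enrichment** — for every annotation pair (A, B),
  log2(observed / expected) edges, where the expectation corrects for
  intra-chromosomal testing and the 1 Mb span cap:

      Expected(A,B) = Σ_C |E_C| · adm_C(A,B) / adm_C(all)

  with adm_C counting same-chromosome node pairs within 1 Mb (unordered
  within-class pairs when A = B).
- **Topology** — closeness 1/Σ nd(u,v), harmonic Σ 1/nd(u,v), betweenness
  Σ |sp(u,x,v)|/|sp(u,x)| (raw and component-size-normalized), plus graphlet
  **orbit signatures**: all 30 connected non-isomorphic graphs on 2–5 vertices
  carry 73 automorphism orbits; each node's 73-orbit count vector is
  proportion-normalized, orbits are clustered by Spearman correlation, and each
  node gets per-cluster scores CS_k = max_{j∈C_k} (O_j − μ_j)/σ_j.
- **Classification** — RBF-kernel SVMs separating broad domains from regular
  promoters and super enhancers from regular enhancers, from 16 network + 7
  genomic features, with MCC-optimized grid search, greedy forward feature
  selection, and ROC/PR/threshold-accuracy reporting.
- **Specificity and SNPs** — SPM cell-specificity of expression
  (SPM = x_c/‖x‖₂), enhancer→promoter target assignment by bounded BFS
  (≤ 4 edges, stopping at the first promoter depth), and a one-sided
  permutation test for phenotype-SNP enrichment in enhancers targeting broad
  domains (E-BD) versus regular promoters (E-P), BH-corrected across
  phenotypes.
- **Synthetic data** — a seeded generator producing peaks, calls, state
  tracks, TSS/expression panels, SNP tables and contact matrices with planted,
  recorded ground truth, so every stage is testable without external data.

## Worked example

```python
from chromnet.synthetic import GeneratorConfig, generate_network_inputs, generate_snps
from chromnet.network import build_network, network_summary
from chromnet.annotate import annotate_states, assign_broad_domains, assign_super_enhancers
from chromnet.enrichment import enrichment_matrix, se_edge_split
from chromnet.specificity import assign_targets
from chromnet.snp import partition_enhancers, enrichment_test

cfg = GeneratorConfig(seed=7)          # 3 chromosomes x 600 nodes, ~4000 edges
data = generate_network_inputs(cfg)
net = build_network(data.calls, data.peaks, extension=250)
annotate_states(net, data.segments, data.tss)
assign_broad_domains(net, data.bd_regions)
domains = assign_super_enhancers(net, data.se_regions)
print(network_summary(net))

em = enrichment_matrix(net)
print(round(em.log2_ratio("broad_domain", "super_enhancer"), 2))
print(se_edge_split(net, domains))

e_bd, e_p = partition_enhancers(assign_targets(net), net)
snps = generate_snps(cfg, data.truth, e_bd, e_p)
for r in enrichment_test(e_bd, e_p, net, snps, n_perm=10_000, seed=7):
    print(r.phenotype, r.k_ebd, r.k_ep, r.p_value, r.bh_q)
```

prints

```
{'nodes': 1772, 'edges': 4023, 'components': 4, 'annotations': {'broad_domain': 119,
 'enhancer': 699, 'insulator': 256, 'other': 158, 'promoter': 360, 'super_enhancer': 180}}
1.77
(141, 27, 0.8392857142857143)
control_1 20 21 0.59344... 0.59344...
control_2 22 20 0.40166... 0.53555...
control_3 21 18 0.34207... 0.53555...
disease 92 18 9.999e-05 0.0004
```

The generator plants a 4× broad-domain↔super-enhancer contact multiplier; the
recovered log2 enrichment of 1.77 reflects it (the expectation is normalized
against the total edge count, which the planted multipliers themselves
inflate slightly). 84% of super-enhancer edges fall within a planted domain,
and the disease phenotype — whose SNPs were planted at 5× rate in E-BD
enhancers — is the only one significant after BH correction (q = 4e-4: 92 of
434 E-BD nodes harbor a disease SNP versus 18 of 445 E-P nodes).

A command-line interface mirrors the library:

```sh
chromnet generate --seed 7 --out data/
chromnet build --calls data/calls.bedpe --peaks data/peaks.bed \
    --states data/states.bed --tss data/tss.bed \
    --broad-domains data/broad_domains.bed --super-enhancers data/super_enhancers.bed \
    --out net.json
chromnet enrich --net net.json --out enrichment.tsv
chromnet topology --net net.json --n-clusters 7 --outdir topo/
chromnet classify --net net.json --tss data/tss.bed --task se --outdir clf/
chromnet snp-test --net net.json --snps data/snps.tsv --out snp_report.tsv
```

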
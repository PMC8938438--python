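# perturbmpra

Design and analysis toolkit for **perturbation MPRA** studies: massively
parallel reporter assays in which predicted transcription-factor binding
sites inside candidate regulatory regions are mutated, and the effect of
each perturbation on reporter transcription is read out over a
differentiation time course from barcode counts.

The package is written for computational biologists who want to (i) pick
*which* motif instances to perturb when the oligo budget is limited, and
(ii) quantify, filter and categorize the perturbation effects once the
DNA/RNA barcode counts are in. Every stage is exercisable end to end on
a bundled synthetic-data generator with planted ground truth, so the
whole workflow is testable without any external download.

## What it computes

**Experimental design.** Regions, motifs and biological properties
(temporal chromatin/expression patterns) form a tripartite graph; the
selection of motif instances is the integer linear program

```
minimize   Σ_r θ_r + 3 · Σ_(t,r)∈E e_{t,r}
subject to Σ_{t∼p} θ_t ≥ 12                      ∀ properties p
           Σ_{r∼p} θ_r ≥ min(17, deg_R(p))        ∀ properties p
           Σ_{t∼r} θ_t ≥ θ_r · min(3, deg_T(r))   ∀ regions r
           Σ_{r∼t} θ_r ≥ θ_t · min(20, deg_R(t))  ∀ motifs t
           e_{t,r} ≥ θ_t + θ_r − 1 ;  e ≤ θ_t, θ_r
           Σ_{t∈T_i} θ_t ≤ 2 per TF;  ≥ 1 per hand-picked TF
           Σ_r θ_r ≥ 0.4·|R|;  Σ_E e ≥ 5·Σ_{E_p} e
           Σ_{T_B} θ_t ≥ 1.5·Σ_{T_S} θ_t;  all variables binary
```

solved with HiGHS (`scipy.optimize.milp`) and re-verified by a
solver-independent constraint checker.

**Library construction.** Each selected instance is perturbed three
ways: replacement by the length-matched prefix of one of two screened
"non-motif" sequences (methods 1–2) or an in-place nucleotide shuffle
(method 3); controls are full-sequence shuffles (SCRAM) and random
12-bp window perturbations (RAND).

**Quantification.** Transcription rates α are estimated by nested GLMs:
a gamma model (log link, `~ timepoint + replicate + barcode`) for latent
construct abundance from DNA counts, then a negative binomial model
(log link, `~ timepoint + replicate`) for RNA counts with the DNA fits
and upper-quartile size factors as exposure offsets. Comparisons are
likelihood-ratio tests between nested designs, BH-corrected per
analysis; activity calls use a MAD-based z-test against the scrambled
null.

**Functional sites and interactions.** A motif instance is a functional
regulatory site (FRS) when it passes four filters (per-timepoint and
temporal PERT-vs-WT deviation, plus distinguishability from the SCRAM
baseline) in the shuffle method and at least one replacement method,
with a consistent effect direction. Activating sites split into
*essential* vs *contributing*, dampening sites into *silencing* vs
*inhibiting*; activation dynamics follow `WT − PERT ~ a + b·WT`.
Double perturbations are tested against the log-additive billboard null
(`y ~ time + Pert1 * Pert2` vs `y ~ time + Pert1 + Pert2`), a pair
being *interacting* when |γ| > 0.5 with BH p < 0.05, consistently
across methods.

## Worked example

The numbered drivers under `analysis/` run one synthetic study end to
end (shared seed in `analysis/common.py`), writing tables to
`results/run/`:

```bash
python analysis/01_design_selection.py
python analysis/02_build_library.py
python analysis/03_associate_count.py
python analysis/04_quantify_activity.py
python analysis/05_call_frs.py
python analysis/06_motif_interactions.py
```

A run at the default demo scale prints, among other things:

```
design graph: 18 regions, 14 motifs, 2 properties, 131 edges
ILP optimum 210: selected 18 regions, 13 motifs, 64 instances
all constraint families satisfied; tightest: property-motif coverage (>= 12 motifs per property) (margin +0.0)
...
association: 8025 barcodes, 79.7% confidently assigned (planted clean fraction 80.0%)
replicate concordance of log-alpha: mean Pearson r = 0.999
alpha vs closed-form ratio: Spearman rho = 0.966
...
consensus FRS set: 50 instances {'activating': 23, 'dampening': 23, 'mixed': 4}
vs planted truth: direction agreement 92.0%, sub-category agreement 92.0% over 50 calls
activation dynamics (delta ~ WT): 23 activators, median R^2 = 0.997
pair classification: {'additive': 3, 'interacting': 2}
vs planted truth: 100% of 5 retained pairs labeled correctly; mean |gamma error| = 0.11
```

i.e. the ILP satisfies every design rule with the property
coverage constraint binding; alpha estimates are replicate-concordant
and rank-consistent with the closed-form RNA/DNA ratio; and the
filter/consensus machinery recovers the planted effect directions,
sub-categories and pairwise interaction labels.

The same pipeline is available as a CLI
(`perturbmpra run-all --seed 3 --out run/`) with granular subcommands
(`simulate`, `design solve`, `counts assoc`, `quantify alpha|ratio`,
`validate`).

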
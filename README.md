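# kiwigenomics

Comparative-genomics analyses for a nocturnal ratite genome, packaged as a
tested, reusable pipeline. The library implements the bespoke statistical
machinery behind a genome study of the kiwi (*Apteryx mantelli*) — a
flightless, nocturnal bird whose genome shows the molecular signatures of
adaptation to life in the dark — and ships synthetic-data generators so
every stage runs and is testable end to end without any sequencing data.

It is aimed at molecular evolution researchers who want these analyses as
composable library functions (plus thin command-line wrappers) rather than
a patchwork of one-off scripts:

- **Branch-model selection screens.** A Goldman–Yang 61-state codon model
  with equilibrium frequencies π, transition/transversion ratio κ, and
  dN/dS ratio ω. The one-ratio model (a single ω for all branches) is
  tested against a two-ratio model (a separate ω on a designated
  foreground branch) by a likelihood-ratio test, 2·(lnL₁ − lnL₀) ~ χ²(1),
  significant above 3.84 at α = 0.05. Likelihoods use Felsenstein pruning
  with analytic branch-length gradients; pairwise ML Ka/Ks is the
  two-taxon special case.
- **Loss-of-constraint dating.** If a branch of duration T switches from a
  constrained era (ω = ω_c) to neutrality (ω = 1) at time t_loss before
  present, the branch-average ω satisfies
  ω·T = ω_c·(T − t_loss) + 1·t_loss, so
  t_loss = T·(ω − ω_c)/(1 − ω_c). Used to date color-opsin
  pseudogenization, a marker of the shift to nocturnality.
- **GC-corrected gene-family copy number.** Collapsed duplications (e.g.
  olfactory receptors) are recovered by dividing each annotated region's
  read depth by the genome-wide mean depth of its 1 % GC bin; the summed,
  floored correction factors c_f estimate the true family size, and ORFs
  are split intact vs pseudogene (frameshift / premature stop /
  truncation).
- **Repertoire diversity.** Per-column Shannon entropy
  H = −Σ p·log₂ p (0 for an invariant column, 4.322 bits for all twenty
  residues equally frequent) summarized per species and compared by the
  exact Wilcoxon signed-rank test (full null enumeration for n ≤ 25).
- **k-mer genome size.** Canonical 19-mer spectra from reads; genome size
  = total k-mers above the error trough ÷ coverage-peak depth; N50 for
  assembly summaries.
- **Enrichment screen.** Upper-tail hypergeometric category enrichment of
  selection-screen gene lists, Bonferroni/Holm FWER control, and a
  three-criterion relaxed filter (p < 0.05, ≥ 3 significant genes, and
  significant genes ≥ 5 % of the category), plus species-specificity
  assignment across foreground choices.
- **Conserved-element screen.** Ultra-conserved non-coding elements
  (> 200 bp, ≥ 95 % human–chicken identity) are globally aligned to
  orthologs and flagged when mismatches + gap columns exceed 5 % of the
  reference length.

## Layout

```
src/kiwigenomics/   library: codon model, selection, repertoire, entropy,
                    genome profile, enrichment, UCNE screen, simulators,
                    pipeline orchestration, CLI
analysis/           numbered drivers reproducing each analysis stage on
                    synthetic data, writing tables under results/
tests/              pytest suite incl. acceptance checks
scripts/            acceptance.py (see "Reproducing the results")
```

## Worked example

Dating the loss of function of the green-sensitive opsin *OPN1MW* from its
fitted branch-average ω = 0.26785 on the focal branch, a constrained-era
ω_c = 0.021 (the average across background bird lineages), and a
focal-branch duration of 50 My:

```python
from kiwigenomics import LossDatingInput, date_loss_of_function

t = date_loss_of_function(LossDatingInput(
    omega_obs=0.26785, omega_constrained=0.021, duration_my=50.0))
print(f"{t:.2f}")   # 12.61
```

The gene went neutral an estimated 12.61 My after the start of a 50-My
branch — i.e. constraint was lost 12.61 My before the branch's end, with
the estimate scaling linearly in the assumed branch duration (7.56 My at
T = 30; see `analysis/02_opsin_dating.py` for the grid and an end-to-end
recovery check on simulated alignments).

The copy-number worked example: a receptor region at 105-fold depth whose
GC content falls in a bin averaging 35-fold genome-wide gets correction
factor 105/35 = 3 — three collapsed copies. Run
`python analysis/03_or_repertoire.py` for the full synthetic repertoire
estimate; it prints

```
annotated 82 loci; corrected estimate 141 (true 141)
intact 86/141 = 61 %
```

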
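# trunkvoc

Analysis pipeline for **longitudinal trunk-volatile monitoring studies**:
non-invasive TD–GC–MS enclosure sampling of tree trunks over months, aimed
at separating the volatiles a tree emits constitutively from those induced
by direct herbivory, by a neighboring infested tree, or by general stress.
The motivating system is a Norway maple (*Acer platanoides*) infested with
the Asian longhorned beetle (*Anoplophora glabripennis*), monitored next to
a non-infested neighbor and a control tree across an acclimation phase, an
abiotic-stress phase (relocation into quarantine) and a long biotic-stress
phase — but every stage is generic over the study design table.

It is written for analytical chemists and chemical ecologists who have a
deconvoluted component table (sample × feature × retention time × area)
and want a reproducible, auditable path from there to classified compounds
and fitted emission dynamics.

## What the pipeline computes

1. **Retention-index annotation.** Experimental linear retention indices
   from a co-analyzed n-alkane ladder (nC₅–nC₁₇), by van Den Dool & Kratz:

       LRI(t) = 100·n + 100·(t − tₙ)/(tₙ₊₁ − tₙ)

   for the bracketing alkanes n, n+1; features are matched to a reference
   library by |LRI_exp − LRI_lit| within a configurable tolerance
   (default 15 index units).
2. **Calibrated quantification.** OLS calibration lines (area =
   slope·mass + intercept, 2–8 levels), surrogate-standard mapping for
   terpenoids without their own standard, and normalization to bark area
   and sampling time: rates in ng dm⁻² h⁻¹, or component area
   ×10⁶ dm⁻² h⁻¹ where no standard exists. A background filter removes
   features whose trunk signal does not exceed twice the ambient level.
3. **Classification.** Detection-frequency (DF) filters and fold-change
   rules: DF ≥ 10% retention over all pooled trunk samples; compounds with
   DF ≥ 50% in *every* tree before biotic stress form the constitutive
   core; the rest are herbivore-induced (de novo at the infested tree, or
   ≥ 2× versus both its own pre-exposure phase and the non-infested
   trees), neighbor-induced (mirror rule), stress-induced (comparable ≥ 2×
   increases in both stressed trees), or unclassified. Sparse comparison
   scopes produce the symbolic ratio marks "ApI" (exclusive), ">"
   (comparison DF < 20%) and "ALB" (de novo).
4. **Dynamics.** Daily mean ± SEM aggregation of duplicate samples,
   nonlinear fitting of the four-parameter 'Extreme' peak function

       y = y₀ + A·exp(−e^(−z) − z + 1),   z = (x − x_c)/w

   (maximum y₀ + A exactly at day x_c, width w), Kendall τ-b grouping of
   correlated emission dynamics within compound classes (single linkage,
   τ ≥ 0.5, p < 0.05), and Kruskal–Wallis + Dunn rank comparisons of
   constitutive emissions between trees and phases.
5. **Reports.** Constitutive and induced summary tables with DF,
   contribution % (summing to 100 per table) and ratio marks, plus a run
   manifest recording every filter-cascade count for auditing.

Because no public dataset accompanies this kind of quarantine study, the
package ships a **synthetic study generator** (`trunkvoc.synthetic`) that
emulates the full design — three trees, 42 sampling days over 188 days in
duplicate, phase-tied induction kernels, multiplicative lognormal noise,
detection censoring — with known planted class labels, so the whole
pipeline is testable end to end.

## Worked example

```bash
python analysis/01_simulate.py            # synthetic study -> results/study/
python analysis/02_annotate_quantify.py   # LRIs, emission rates
python analysis/03_classify.py            # filter cascade + labels
python analysis/04_dynamics.py            # peak fits, tau groups, rank tests
python analysis/05_report.py              # report tables + manifest
```

With the default seed this prints, among other things:

```
primary labels:
label
constitutive        30
hipv                15
neighbor_induced     6
stress_induced       4
4 constitutive compound(s) carry an induced secondary flag: 2-butanone, 2-methylbutanal, 3-carene, alpha-pinene
planted-label recovery: 100.0% of 55 compounds
fitted 29 series, 29 converged
  beta-ocimene @ ApI: peak day 36.0, width 4.4 d, adj R^2 0.994
tau grouping: 4 multi-compound group(s) of 23 compounds
constitutive table: 30 compounds, contributions sum to 100.01%
  nonanal: LRI 720, DF 100%, 26.56% of the blend
```

Reading this: all 55 planted compounds were recovered with their true
class; four constitutive volatiles additionally satisfied an induced rule
(their primary label stays constitutive, the induced rule becomes a
secondary flag); β-ocimene's infested-tree emission peaks near day 36 —
about two weeks after beetle exposure at day 20 — and an aldehyde-dominated
constitutive blend is led by nonanal. The same stages are available as a
CLI (`trunkvoc simulate|annotate|quantify|classify|dynamics|report|run-all`)
driven by a YAML config.

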
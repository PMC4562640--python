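# phycosignal

Do the traits that decide competition among freshwater green algae — minimum
resource requirements (R*), growth responses to nitrate, phosphate and
light, stoichiometry, cell size — carry phylogenetic signal? `phycosignal`
is an analysis pipeline for that question. It estimates competitive traits
from plate-reader growth curves, measures phylogenetic signal with three
complementary statistics, tests whether phylogenetic distance predicts
trait differentiation, and fits five models of continuous trait evolution
with an Akaike-weight selection rule and a parametric-bootstrap
Brownian-motion null.

The pipeline is aimed at comparative ecologists working with a phylogram
and a species × trait table, plus anyone who needs the upstream step of
turning raw well-plate fluorescence into Monod parameters and R*.

## The models at the core

**Growth side.** Per-well exponential rates r come from OLS of ln RFU on
day with end-trimming of density-limited readings. The growth–resource
response is Monod, μ(R) = μ_max·R/(R + μ_max/α) − D, optionally the
hump-shaped light-optimum form (AIC selects), and the zero-net-growth
resource level is R* = D·μ_max/(α·(μ_max − D)) — the classic R* of resource
competition theory: the lower a species' R*, the stronger a competitor it
is for that resource.

**Comparative side.** For each trait on the tree: Blomberg's K (K = 1
under Brownian motion; randomisation test), Pagel's λ (ML over the
covariance multiplier; likelihood-ratio test against λ = 0), Moran's I with
inverse-patristic-distance weights (randomisation test), and a Mantel test
of patristic versus Euclidean trait distance. Five trait-evolution models —
BM, Ornstein-Uhlenbeck (stabilising pull α toward an optimum), white noise
(no tree effect), and the δ and λ tree transforms — are fitted by maximum
likelihood with σ² and the root state profiled analytically; Akaike weights
pick a best model only when one reaches weight ≥ 0.5 ("no choice"
otherwise), and δ̂/λ̂/α̂ are flagged when they fall outside 95% CIs built
from 1,000 simulated Brownian walks on the same tree.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with known truth (each trait's name encodes the model that generated
it):

```sh
python analysis/01_simulate_study.py      # tree + traits + plate data
python analysis/02_growth_traits.py       # growth curves -> Monod -> R*
python analysis/03_phylo_signal.py        # K / lambda / Moran's I + Mantel
python analysis/04_model_selection.py     # five-model AIC weights
python analysis/05_bootstrap_null.py      # BM bootstrap CIs + flags
```

Step 02 prints, per species, the fitted Monod parameters and R* against the
generating truth — with the default 5% noise every one of the 12 simulated
species comes back within 10%:

```
species_id  form  alpha_slope   mu_max    rstar  true_rstar  rstar_rel_err
       s01 monod     0.037503 0.896999 1.411931    1.429205       0.012086
       s02 monod     0.010661 0.851247 4.982433    5.063151       0.015942
       ...
R* within 10% of truth for 12/12 species
```

Step 03 prints the signal table (excerpt):

```
         trait     K   p_K  lambda  p_lambda  moran_I   p_I  N
          bm_1 1.236 0.001   1.000       0.0    0.478 0.001 59
          wn_1 0.124 0.039   0.000       1.0    0.050 0.237 59
  tippy_delta3 0.325 0.001   0.820       0.0    0.278 0.005 59
```

Brownian traits show K ≈ 1 and λ = 1 with small p; white-noise traits show
λ = 0 and no Moran/Mantel signal. (Note `wn_1`'s K p-value of 0.039: a
randomisation p can land below 0.05 by chance, and K alone is a shaky basis
for claiming signal — the λ, Moran and Mantel columns tell the real story.)
Step 04 then selects δ for the tip-concentrated trait (δ̂ = 4.7, weight
0.68) and OU for the stabilising-selection trait, while BM traits spread
weight across BM and its nested transforms (BM weight ≈ 0.46, "no
choice") — the weights row, not just the label, is the result. Step 05
flags exactly the non-Brownian traits as outside the BM-null CIs.

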
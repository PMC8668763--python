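# streamfd

Multidecadal functional-diversity analysis of stream macroinvertebrate
communities from fuzzy-coded biological traits.

## The problem

Long-term monitoring of benthic macroinvertebrates (insect larvae, worms,
molluscs) often shows taxonomic recovery — richness rising over decades as
acidification or nutrient stress abates — but richness alone says nothing
about whether the *functions* carried by those taxa recovered too. This
package implements the standard distance-based trait toolkit used to answer
that question for an annual community time series:

1. **Trait space.** Taxa are scored by fuzzy coding: within each of ~11
   biological trait groups (voltinism, body size, feeding habit, ...) a taxon
   distributes affinity over the group's modalities, scaled so each group
   block sums to 1. A Gower dissimilarity matrix over all modalities
   (`d_ij = mean_k |x_ik − x_jk| / range_k`) is embedded by principal
   coordinates (PCoA, square-root correction by default) into `m = 13` axes.
2. **Per-year metrics.** For each survey year with relative abundances `p_i`:
   - FRic — convex-hull volume of the present taxa, standardised by the
     pool ("overarching") hull, in (0, 1];
   - FEve — regularity of abundance along the minimum spanning tree,
     `FEve = (Σ_l min(PEW_l, 1/(S−1)) − 1/(S−1)) / (1 − 1/(S−1))`;
   - FDiv — abundance-weighted deviance from the mean distance to the
     hull-vertex centroid;
   - FDis — `Σ p_i ||x_i − c||` with `c` the weighted centroid;
   - RaoQ — `Σ_ij p_i p_j d_ij`, scaled by the series maximum;
   - CWM — `cwm_k = Σ p_i x_ik` per modality;
   - FDist — abundance-weighted mean distance of each taxon to all others
     in its community (functional distinctiveness).
3. **Inference.** A name-shuffling null model (taxon labels permuted over the
   pool) turns richness-confounded metrics into standardized effect sizes;
   taxonomic and functional turnover are `(gains + losses) / pooled richness`
   between consecutive surveys (modalities with CWM > ε act as the "species"
   for the functional variant); trends are tested with the Hamed–Rao
   autocorrelation-corrected Mann–Kendall test, OLS, and a GCV-penalized
   cubic regression spline; functional redundancy is read off the slope of
   FDis/RaoQ against richness; per-clade distinctiveness is compared with
   ANOVA + Tukey HSD and compact letters.

A synthetic-data module generates trait pools with clade-correlated
syndromes and community series with rising richness, declining evenness and
a clade rising to dominance, so the entire pipeline is testable without any
field data.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic scenario and write tidy CSVs under `results/`:

```bash
python analysis/01_simulate.py --seed 1     # traits.csv, community.csv
python analysis/02_trait_space.py           # Gower + PCoA
python analysis/03_fd_metrics.py            # per-year metric suite + CWM
python analysis/04_null_models.py --seed 1  # name-shuffling SES
python analysis/05_turnover.py              # taxonomic vs functional turnover
python analysis/06_trends.py                # MK + OLS + spline per metric
python analysis/07_redundancy_and_groups.py --seed 1
```

Selected output (seed 1):

```
trait space: m = 13 axes (sqrt correction), quality = 0.719 of positive-eigenvalue variation retained
taxonomic turnover: mean 0.415 over 23 pairs
functional turnover: mean 0.010
functional <= taxonomic in 23/23 pairs; paired t = 29.7 (df 22, p 3e-19)
significant monotone trends at 5%: richness, fric, log10_fric, feve
fdis ~ richness: slope -2.17e-03 +/- 1.75e-03 (p 0.230) -> no detectable relation: high redundancy
```

Reading: the reduced trait space captures 72% of the trait variation; taxa
churn between surveys (turnover 0.42) while the community's trait composition
barely moves (0.01), richness rises and evenness falls significantly, and
adding taxa does not add functional dispersion — the signature of a
functionally redundant community.

The same pipeline is exposed as a CLI (`streamfd simulate|run|metrics|trends`)
and as one call, `streamfd.run_full_analysis(...)`, which accepts either a
synthetic scenario or your own trait/abundance/mapping CSVs (trait table wide
with a two-row group/modality header; abundance table wide with a `year`
column; mapping a two-column CSV).

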
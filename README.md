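# sdmshift

Presence-only species distribution modelling (SDM) with boosted
regression trees, temporal transfer to past and future environmental
conditions, and quantitative indices of distribution-range and
niche-space change.

## The problem

Marine benthic species — the motivating case is Southern Ocean
echinoids on sub-Antarctic plateaus — are sampled opportunistically:
museum and cruise records tell us where a species *was found*, never
where it is absent, and survey effort is strongly clumped in space.
Predicting how such species respond to warming and freshening requires

1. fitting a habitat-suitability model to presence-only records while
   cancelling survey bias,
2. projecting that model onto environmental layers of other time
   periods, and
3. measuring how much the predicted distribution and the occupied
   environmental niche move.

`sdmshift` implements that full workflow as a tested Python library,
driven by a synthetic *virtual species* world in which every planted
quantity (niche optimum, collinear predictors, imposed warming, survey
bias) is known exactly, so each stage can be validated against ground
truth.

## The method

**Model.** Boosted regression trees (BRT) for a binary
presence/background response under Bernoulli deviance: starting from the
logit of the prevalence, each stage fits a least-squares regression tree
with `tc` splits to the current gradient *y − p* on a random bag of
`bf·n` rows, applies a single Newton step per terminal node and adds the
tree shrunk by the learning rate `lr`. The defaults follow the classic
ecology calibration (`tc = 2`, `bf = 0.75`); `lr = 0.01` for desk-scale
data, with the literature-faithful `lr = 0.0001` preset available as
`sdmshift.PAPER_PRESET`. The number of trees is chosen by k-fold
cross-validated predictive deviance.

**Bias correction.** Background points are drawn with probability
proportional to a Gaussian kernel density estimate of *visited* cells
(cells holding any record of the target group), so presences and
backgrounds share the same effort bias. Background count equals
presence count and the draw is replicated (default 100-fold).

**Predictor filtering.** Pairwise Spearman |ρ| > 0.85 and stepwise
variance-inflation-factor elimination (drop max VIF while > 5).

**Evaluation and binarization.** Presence-vs-background AUC
(Mann–Whitney, ties ½); suitability maps are binarized at the MaxSSS
threshold (observed score maximizing sensitivity + specificity).

**Change indices.** For suitability maps *p* (reference period) and *q*
on a shared extent, scaled by the reference occupancy:

    E_occupied    = Σᵢ pᵢ
    E_instability = Σᵢ |qᵢ − pᵢ| / E_occupied(ref)
    E_overlap     = Σᵢ pᵢ·qᵢ   / E_occupied(ref)

reported as mean ± sd over the background replicates, alongside
suitable-area pixel counts.

**Niche space.** Suitable cells inside a focal box contribute their
values of the two most influential predictors; the occupied subspace is
their convex hull (shoelace area, polygon centroid), compared across
periods by centroid displacement, area ratio and clipped intersection.

## Worked example

`examples/04_shift_recovery.py` plants a +2 °C uniform warming in a
world whose temperature declines poleward at 0.8 °C per degree of
latitude, fits a BRT to a biased survey of a temperature-limited
species, and projects it onto the warmed stack:

```
imposed warming:                +2.00 degC
expected latitudinal shift:     -2.50 deg
recovered latitudinal shift:    -2.53 deg
hull centroid shift (temp):     +2.00 degC
instability present vs future:  1.297
instability replicate noise:    0.169
```

The suitable area moves poleward by warming/gradient = 2.5° of latitude
(recovered −2.53°), the occupied-niche hull of a non-dispersing
population shifts along the temperature axis by exactly the imposed
warming, and the present-vs-future instability signal sits an order of
magnitude above the replicate noise floor.

`examples/03_project_and_indices.py` runs the replicated protocol
end-to-end and prints the change-report table; with the default world
(+2 °C future warming, −0.5 °C past cooling) it yields
`E_instability = 0.148 ± 0.007` against the past but `0.575 ± 0.036`
against the future — the predicted reorganization to come dwarfs the
historical one.

The other examples cover world construction (`01_simulate_world.py`)
and predictor selection plus a single fit (`02_select_and_fit.py`).
A thin CLI mirrors the stages
(`sdmshift simulate | select | background | fit | evaluate | indices |
niche | run | report`); `sdmshift run --out dir/` executes the whole
protocol from a YAML config.

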
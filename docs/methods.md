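# Methods

## Model

ghbfit trains a pairwise hydrogen-bond correction potential for RNA force
fields. The correction acts on hydrogen--acceptor distances through a
switching function, with one trainable strength per hydrogen-bond *type*:
two donor classes (base -NH groups; the sugar 2'-OH) crossed with six
acceptor classes (base N, base carbonyl O, nonbridging phosphate O,
bridging phosphate O, sugar O2', sugar O4') give 12 types and 12 unitless
strengths lambda. The per-frame feature n_j(x) is the smooth count of
formed type-j bonds: the sum over pairs of that type of a switching
function that is 1 below r_low, 0 above r_high and interpolates in between
(default 2.0-3.0 A on the H..acceptor distance, linear shape; a cubic
smoothstep is available). Internally the per-pair count lives in [0, 1];
the -1..0 convention, identical up to an additive constant, is used only
at the PLUMED interface. Energies are reported externally as k_B*T*lambda
(k_B*T = 0.5922 kcal/mol at the default 298 K, computed from the gas
constant; conversion happens only at I/O boundaries).

With correction exponent f(x, lambda) = -sum_j lambda_j n_j(x), the
modified ensemble is P(x, lambda) ~ P0(x) exp(-f), so positive lambda_j
supports formation of type-j bonds and d<n_j>/d lambda_j equals a
reweighted variance, hence is non-negative by construction. Frame weights
are computed in log space with a max-shift; exponents up to ~700 in
magnitude do not overflow.

## Cost function

Observables are mapped to experiment through forward models: NOE effective
distances <r^-6>^(-1/6); unobserved-NOE bounds treated one-sided
(penalized only when the effective distance falls below the bound -- an
absent cross-peak implies the distance was never short); scalar couplings
via the Karplus equation averaged over frames (fast-exchange convention:
the coupling is averaged, not the torsion); and native-state populations
as reweighted means of a precomputed binary indicator (eRMSD-based
labelling is upstream of this package). The per-system error chi^2 is the
*average* squared standardized discrepancy over its M observables; the
total data cost is the omega-weighted linear combination over systems,
deliberately not divided by sum(omega) (the per-system chi^2 values are
reported alongside so either convention is recoverable). All gradients are
analytic, using d<O>/d lambda_j = cov_w(O, n_j).

## Regularization

Five penalties are supported, one at a time: L2 sum (lambda - lambda0)^2
(Gaussian prior on the parameters), L1 sum |lambda - lambda0| (Laplace
prior, sparsity-promoting; the subgradient at the kink is taken as 0 so
lambda0 is a fixed point), the inverse Kish size sum w^2 of each
reweighted trajectory, the inverse relative Kish size sum w^2/w0, and
exp(KL(w||w0)). The ensemble-dependent penalties are combined across
systems with a plain LogSumExp, ln sum_i exp(v_i), which effectively picks
the largest penalty so every system retains statistical weight. The
relative forms equal exactly 1 at lambda = lambda0 and grow as the
posterior departs from the prior; the Kish penalty instead favors uniform
weights, so with nonuniform priors its minimizer is *not* lambda0 -- a
property the tests assert. Hard box constraints
|lambda - lambda0| <= lambda_max (default 1 kcal/mol in k_B*T units) act
as an L-infinity term preventing parameter divergence and are enforced by
the optimizer bounds.

Numerical notes: the LogSumExp and its softmax gradient use the shifted
(overflow-safe) forms; the relative-entropy penalty exponentiates the KL
divergence directly and is validated finite, which is ample within the
default box at desk-scale feature counts; 0*log 0 := 0 in the divergence.

## Optimization

Box-constrained quasi-Newton (L-BFGS-B) with the analytic gradient,
ftol 1e-14 and projected-gradient tolerance 1e-8, starting from lambda0
plus seeded uniform restarts inside the box (5 by default for `fit`). The
returned optimum never loses to lambda0 itself. Cross-validation defaults
to a single start at lambda0: a coordinate whose feature column is
identically zero on a training view then provably stays at lambda0 (its
gradient component is identically zero), which is the behaviour the
leave-one-system-out analysis measures.

## WHAM merging

Runs generated under K different parameter sets are merged with the
binless WHAM / multistate-reweighting equations, solved by damped
fixed-point iteration on the per-run log free energies (gauge f_1 = 0,
damping 1.0 by default, tolerance 1e-10 on the max change of the
normalized log-weights, at most 1e5 iterations). The input is the
frames x K matrix of reduced energies; the target potential defaults to
the first column, so a single run or duplicated indistinguishable runs
return uniform weights, and passing a zero target for a single biased run
reduces to inverse-Boltzmann reweighting. Output is invariant to adding a
constant to any energy column.

## Cross-validation and model selection

Three protocols: SEGMENTS splits every trajectory into contiguous equal
blocks (5 by default -- contiguity respects the temporal correlations of
replica-exchange ground replicas) and leaves one block out jointly across
systems; OBSERVABLES leaves one (system, observable-group) unit out per
fold (the two tetraloop populations count as separate units, giving the
7-fold structure); SYSTEMS leaves one whole system out. For every alpha on
a logarithmic grid (default 25 points over 8 orders of magnitude, 1e-4 to
1e4) the model is refitted per fold -- the strict reading of per-fold
training -- and scored by the unregularized cost on the left-out view.
best_alpha minimizes the mean validation error with exact ties broken
toward the stronger regularization; `select_model` additionally treats the
regularization kind as a categorical hyperparameter, picks the best curve
and refits on all data. A fitted strength can be reset post hoc
(`manual_override`) to its reference or to zero, mirroring the removal of
a term whose motif is absent from the training set; costs are then
re-evaluated.

## Synthetic data

The generator emulates the statistical interfaces of a realistic training
set, not real RNA ensembles: a latent binary native/non-native state per
frame; per-type bond counts binomial with logit-linear state dependence
(well-conditioned exponential-family reweighting); per-frame observable
inputs tied to feature columns with independent jitter; "experimental"
values computed as exact reweighted averages at the ground truth lam_true
plus Gaussian noise of noise_scale * sigma. Defaults: 50,000 frames per
system; lam_true interior to the box; a tetramer with 8 NOE + 4 uNOE + 9
J-couplings in 5 groups (sigma 0.1 A and 0.5 Hz), a mildly biased known
prior, and active types 0..10; two tetraloops with one population
observable each (sigma 0.05) and uniform priors. The UUCG-like loop's
native state depends only on type 11, inactive everywhere else; the
GAGA-like native type 10 is also active in the tetramer. This engineered
asymmetry reproduces the leave-one-system-out phenomenology: with the
UUCG-like system left out, coordinate 11 is unconstrained and its
validation error cannot drop much below the reference error, whereas the
GAGA-like fold improves dramatically.

Because targets are computed from the very frames being reweighted,
noise-free recovery is exact up to optimizer precision; passing tests
therefore demonstrate the correctness of the estimator and machinery, not
robustness to forward-model error, autocorrelation or sampling bias, none
of which the generator emulates.

## Test problem sizes and known limitations

Tests run the suite at 2,000-8,000 frames for structural checks and at the
canonical 50,000 frames for parameter recovery; the segment-CV flatness
check uses the gap between the small-alpha validation error and the curve
minimum measured against the reference-parameter error scale (median over
three seeds), because the strongly reweighted tetraloop makes raw
segment-to-segment ratios fluctuate at desk-scale frame counts. Kish
effective sizes of the heavily reweighted tetraloop drop to a few percent
of the frame count -- intentional, as it exercises the regularizers'
reason for existing. No autocorrelation-aware effective sample size, MBAR
covariance estimation, angle-dependent hydrogen-bond criteria or
neighbor-list optimization is provided; frame counts are expected to be
desk-scale.
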
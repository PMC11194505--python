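# Methods

## Model

`synhebb` simulates networks of rate-coding excitatory (E) and inhibitory
(I) neurons that receive tuned feedforward input (F). Membrane potentials
follow leaky integration of the synaptic drive,

    tau_A du_A/dt = -u_A + W_AF r_F + W_AE r_E - W_AI r_I ,  A in {E, I},

integrated with the explicit Euler method at step `dt` (rates for the drive
are taken from the pre-step state). Firing rates are a rectified power law
of the potential, `r = a [u - b]_+^n`; the default exponent n = 2 puts the
network in the supralinear (expansive) regime, and n = 1 with b = 0 gives
the linear neuron used by the fixed-point theory.

All weights are nonnegative; a projection's sign is fixed by its type
(Dale's law by construction). Plastic weights grow by a plain Hebbian rule,
`dW_AB/dt = eps_AB r_A r_B^T`, and are divisively renormalized after every
integration step so that each neuron's *total* weight of each synapse type
is constant: the recurrent-excitatory row and the plastic feedforward row
are pooled and scaled to the budget `W_AE`; the inhibitory row is scaled
separately to `W_AI`. The two budgets are independent resource pools —
this synapse-type-specific competition, not a firing-rate set point, is
what stabilizes learning. The classic alternative
(`dw_EI/dt = eps (r_E - r0) r_I`, unnormalized, entries clipped at zero) is
implemented as a baseline.

Division by a row's total is undefined when the total is zero; such rows
are left unchanged (with a warning) until their neuron first fires. Autapse
diagonals of W_EE and W_II are held at zero by default (a Hebbian autapse
is pure self-amplification and the circuit diagrams the parameter sets
describe contain none); the flag is configurable, and allowing autapses
changes none of the qualitative results reported by the test suite.

## Input model

A grating of orientation theta and contrast c drives input channel j at
`c * A_F * exp(-d(theta, thetaF_j)^2 / (2 sigma_F^2))`, with d the angular
distance on the 180-degree orientation circle and channel preferences
evenly spaced. Training presents gratings of uniformly random orientation,
each held for 200 ms. Plaids superpose additively at the input stage, so
any sublinearity of the network's plaid response is attributable to
recurrent dynamics. For the strongly recurrent experiments, feedforward
weights are static Gaussian tuning profiles (width `sigma_theta`) row-
normalized once at setup and excluded from the recurrent excitatory pool.

The width entry for these experiments is implemented as
`sigma_F = sigma_theta = 30/sqrt(2) ≈ 21.2 degrees`, so that the
composition of input tuning and weight tuning yields an effective
feedforward drive profile of width 30 degrees — the stimulation pattern of
the stabilized-supralinear-network studies this parameter set derives
from. With 15-degree widths instead, the trained network's
contrast-response function is non-monotone above the training contrast and
cross-orientation suppression has no margin; with the 30/sqrt(2) reading
the contrast-response is monotone and suppression is robust.

## Mirrored inhibitory inputs

The single-neuron experiments clamp the inhibitory population's rates to
the feedforward rates (`r_I = r_F`): inhibitory input neurons are exactly
as stimulus-selective as the excitatory ones. Because these are *input*
neurons, their contribution to the E drive uses the current stimulus, like
the `W_AF r_F` term, rather than a lagged integrated state. With the
integration step equal to the stimulus duration, the lagged alternative
would make inhibition permanently one stimulus stale; the target-rate loop
of the classic rule then never closes and inhibitory weights grow without
bound.

## Experiments and their timescales

Divisive normalization makes each plastic row an exponentially forgetting
average of Hebbian outer products; the forgetting time is
`norm / (per-step row inflow)`. For the strongly recurrent networks this is
roughly 9,000 stimuli, and training runs use 20,000–24,000 stimuli (at
least two forgetting times) so the learned structure reflects the stimulus
statistics rather than the initialization. The fully plastic
decorrelation network trains for 30,000 stimuli — the plateau of its
recurrent connectivity structure, where response selectivity, assembly
structure (similar-tuning neurons most strongly connected) and E/I input
co-tuning are established. Problem sizes follow the published parameter
sets. The center/surround networks are used at full size (80 E per
region): at half size with the same per-neuron weight budgets the
operating point shifts and the iso/cross ordering of surround suppression
inverts, so the experiment does not scale down.

Center/surround training diverges when E-originating recurrent weights
start at zero: the first region-separated stimulus imprints the entire
W_EE budget onto one region's co-active neurons and the resulting loop
gain is unstable (this is a property of the continuous dynamics, not of
the Euler step — halving dt reproduces it). These presets therefore
initialize all recurrent weights from the normalized random draw; both
training-statistics modes use the same initialization so their learned
connectivity is comparable.

## Probing conventions

Preferred orientations are the argmax of the steady-state response
(20 tau settling from rest, contrast 1.0) over a 1-degree grid, ties
resolving to the smallest angle (within floating-point tolerance).
Connectivity profiles average weights in 18 signed bins of 10 degrees
over preferred-orientation difference, normalized by the block maximum;
empty bins are missing (NaN), not zero. Semi-saturation contrast is the
half-dynamic-range crossing of a contrast-response curve, linearly
interpolated on log contrast.

Masking probes: the trained supralinear network *facilitates*
cross-oriented probes at contrasts below its training contrast (the
expansive regime sums superlinearly — a regime in which cross-orientation
facilitation is also observed experimentally) and suppresses at and above
it. The plaid-sublinearity check therefore uses matched full-contrast
(c = 1) components, and the semi-saturation shift is evaluated for mask
contrasts at and above the training contrast (0.5); both choices are fixed
here, not tuned per run. Surround-suppression probes hold the center
grating at full contrast while the surround contrast increases, iso- or
cross-oriented.

## Linear theory

For linear neurons the expected feedforward drift is
`<dw/dt> ∝ C w - gamma w` with C the *uncentered* second-moment matrix of
the inputs (callers wanting centered statistics must center the ensemble
first); fixed points are eigenvectors of C, and with nonnegative inputs
the Perron eigenvector is the stable outcome, which the simulator
reproduces. With a mirrored inhibitory stream the joint drift of
(w_E; w_I) is governed by the block matrix with negated inhibitory
columns; gamma and rho are realized as block-wise mean Hebbian drive over
the weight sum — the unique scalars that preserve the L1 norms the
divisive normalization maintains. Degenerate leading eigenvalues are
reported, never silently resolved.

An eigencircuit's effect on its input mode's attraction is
`lambda_eig = sum_i var(r_E,i) - sum_j var(r_I,j)`, and collapse of all
tunings onto one mode is prevented when `N_E var_E < N_I var_I` (strict
inequality; the boundary does not prevent). The toy fixture realizes the
two regimes with four one-hot input modes of graded but close amplitudes
(1.9, 1.8, 1.7, 1.6): the mild ordering gives the uninhibited network a
well-defined collapse target, while a steeper gradient would funnel the
inhibited network's neurons onto the weakest mode instead of spreading
them.

## Known limitations

The fully plastic decorrelation network does not reproduce the
dip-and-recover trajectory of population tuning uniformity. In this
implementation, tiling of excitatory preferred orientations forms early
(about 10,000 stimuli) and then slowly *coarsens*: similarly tuned E pairs
merge, uniformity declines monotonically, and after very long training
(160,000 stimuli) the E population occupies only a few orientation
clusters, while the inhibitory population tiles the space throughout and
excitatory/inhibitory input currents remain precisely co-tuned
(cosine ≈ 1). The coarsening is driven by recurrent E-E plasticity:
freezing W_EE at zero restores stable tiling. It is insensitive to autapse
handling, initialization, update order, and onset-transient gating, and it
occurs even though the measured rate variances satisfy the
collapse-prevention inequality by a wide margin — that inequality rules
out full single-mode collapse (which indeed never occurs) but not partial
clustering. Consequences for the test suite: after training, excitatory
preferred orientations typically occupy 6–8 of 10 orientation bins rather
than tiling almost perfectly, and final uniformity sits below its
early-training value.

The synthetic gratings are noiseless, the dynamics deterministic, and the
orientation circle the only stimulus dimension; passing tests show the
learning rules organize connectivity under these idealized statistics,
not that they do so for natural inputs. Conductance-based or spiking
dynamics, synaptic delays, and homeostatic scaling of the budgets
themselves are out of scope.
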
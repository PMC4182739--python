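# Methods

## Coding-frame model

Evolution of the coding frame (+1) is the M0 codon model: a reversible
continuous-time Markov chain on the 61 sense codons with rates
q_xy = π_y κ^[transition] ω^[nonsynonymous] for single-nucleotide
neighbours, zero otherwise, and zero into stop codons (a premature stop
is assumed lethal in a functional protein). Codon sites are independent
and the chain is assumed stationary, so a sequence is an i.i.d. draw from
the codon usage π. The generator is divided by Σ_x π_x(−q_xx) so that t
is measured in expected substitutions per codon; this makes parameter
settings comparable and cancels everywhere a flux ratio is taken.
Parameters: κ ≥ 0 (dimensionless, default 1), ω ≥ 0 (dimensionless;
0.3 and 3.0 are the canonical purifying/adaptive scenarios), t ≥ 0
(substitutions per codon). By reversibility the stationary distribution
equals the input usage; the model matrix carries it explicitly so the
reducible ω = 0 chain (synonymous moves only) stays usable.

## Frame projection

Adjacent codons evolve independently, so the di-codon process on 61²
ordered pairs has generator Q⊗I + I⊗Q (Kronecker sum; exactly one codon
changes per event) and stationary distribution π⊗π. Each alternative
frame reads one codon inside the 6-nucleotide window; the window
convention (+2 → positions 2–4, …, −2 → complement of positions 5,4,3)
is fixed by the requirement that coding-frame codon positions 1 and 2
map onto −2 positions 2 and 1, and is confirmed by the exact
reproduction of the degrees-of-freedom table.

The frame process is obtained by marginalization: for frame states
x ≠ y,

    q^f_xy = Σ_{d: s(d)=x} [π(d)/π^f(x)] Σ_{d': s(d')=y} A(d, d'),

i.e. flank positions are averaged over their stationary distribution
conditional on the observed sub-codon — the only weighting consistent
with the stationarity assumption. With it, π^f (the marginal of π⊗π) is
exactly stationary for Q^f. Frames ±1 use 61-state containers (frame −1's
states are the reverse complements of the sense codons, so TTA, CTA and
TCA never occur); frames ±2/±3 use all 64 codons — stop codons are
ordinary states there. States with zero marginal support are kept with
zero rows and flagged unreachable.

The projected process is *treated* as Markov. It is not exactly so: the
matrix exponential of Q^f differs from the exact marginalized product
channel by up to ≈0.05 entrywise at t = 1 (measured for the κ=1, ω=0.3
configuration). The simulator tests therefore compare empirical
transition frequencies against the exact marginal, with exp(Q^f t)
checked as an approximation at the 0.05 level; the empirical-channel
consistency check uses base time t₀ = 0.1, where the discrepancy stays
within 0.02 across 1–4 composition steps.

## Selection pressure per frame

ω^f = d_N/d_S is computed on rate matrices (no time dependence):
synonymous and nonsynonymous stationary fluxes ρ_S, ρ_N under Q^f are
normalized by the same fluxes under an ω = 1 reference matrix built from
the frame's own π^f and the shared κ. Scaling factors cancel, giving the
exact identity ω^{+1} = input ω (verified to 1e−10). Stop handling in
frames that contain stop states: the stop label is a 21st symbol —
stop↔stop substitutions count as synonymous, stop↔amino-acid as
nonsynonymous — and the reference matrix does not zero stop transitions,
since no functional protein is being preserved in those frames. This is
the main modelling judgment call; it keeps the flux partition exhaustive
and reproduces the expected +1/−2 selection coupling.

## Genetic noise

The frame channel P^f(t) = exp(Q^f t) is aggregated to a 20×20
amino-acid channel: stop rows/columns removed (rows renormalized), codons
pooled within each amino acid with weights π^f conditional on the amino
acid. Genetic noise is the conditional entropy with uniform weighting
over the alphabet, H^f(Y|X) = mean row entropy in bits, bounded by
log₂ 20 ≈ 4.32; sequence similarity is the uniform-input mutual
information I = H(Y) − H(Y|X). If a frame's realized alphabet is smaller
than 20 (possible with sparse usage vectors), the affected symbols are
dropped and flagged and the bound becomes log₂ of the reduced alphabet.
The half-information time solves H^f(t) = log₂(20)/2 by bisection on
[0, 20] to 1e−4; the threshold uses the full 20-letter bound by default
(a `threshold` argument selects the reduced-alphabet variant), and
published-table comparisons round to one decimal.

## Degrees of freedom of the code

For every ordered pair (A1, A2) from the 21-symbol alphabet (20 amino
acids + stop), all di-codons translating to the pair are enumerated and
the distinct translations of the frame sub-codon counted, stop counting
as its own symbol. The reported statistic is the unweighted mean over
all 441 pairs, rounded half-up to 2 decimals. Flags expose the nearby
variants (exclude stop from pairs and/or counts); the defaults are the
variant that reproduces the published table (+2: 2.94, +3: 2.93,
−1: 2.67, −2: 1.59, −3: 3.12) and are recorded in CLI output metadata.
The enumeration is its own oracle; tests cross-check a loop-permuted
second enumeration.

## Monte-Carlo verification

Sequences of 2×10⁵ i.i.d. codons (the default verification scale, chosen
for ≈3σ discrimination of the frame marginals) are drawn from π and
evolved by row-sampling from P(t) — equal in law to simulating the
continuous-time chain over a fixed horizon. Sliding 6-nucleotide windows
over consecutive codon pairs gives empirical frame codon frequencies
(total-variation distance to π^f under 3·√(64/n)) and, pairing ancestral
with descendant windows, empirical frame transition frequencies. All
randomness flows through recorded integer seeds.

What the generator emulates — and does not: synthetic usage vectors are
Dirichlet draws with the few-fold frequency spread typical of bacterial
codon bias, and sequences are i.i.d. stationary codons. Real genomes
have amino-acid composition structure, intragenomic usage heterogeneity,
site-to-site rate variation and non-stationarity, none of which the
model represents; passing tests therefore validate the mathematics of
the projection and the information measures, not the fit of M0 to any
particular genome. Analyses of a real genome enter only through its CDS
codon-usage vector.

## Empirical-channel robustness mode

An externally supplied row-stochastic codon matrix replaces exp(Qt):
time points are integer matrix powers (the only composition available to
a discrete channel), the di-codon channel is the product channel (both
codons transition independently), and marginalization uses the same
conditional flank weighting, with the supplied usage as the flank
distribution by default. The projection lives on the full 64-codon
container; unsupported states get identity placeholder rows and are
flagged, and entropies are computed on the supported block. This
construction is validated by the model-consistency check above and by
the qualitative ordering (entropy lowest in +1, then −2, for channels
generated under purifying selection); no claim is made that it matches
any particular published estimation procedure.

## Numerical choices

Matrix exponentials use scipy's scaling-and-squaring; stationary
distributions use an SVD null space (raising on multi-dimensional null
spaces, with entries clipped at −1e−12 for round-off); generators
validate row sums at 1e−10 and stochastic matrices at 1e−8. Codon order
is lexicographic everywhere (AAA … TTT, stops removed in 61-state
objects) and every matrix carries its state labels. CDS codon counting
includes the initiation codon, excludes the terminal stop, skips
ambiguous codons without imputation, and truncates (with a warning)
trailing bases of CDS whose length is not a multiple of 3. Zero usage
entries are permitted; `CodonUsage.with_floor` provides an optional
floor for downstream stability. TSV outputs use 10–12 significant
digits.

## Known limitations

- M0 only: no site classes, no GTR nucleotide exchangeabilities, no
  rate heterogeneity, no indels.
- Single-frame selection: the model imposes selection in +1 and *derives*
  the other frames; it cannot represent joint selection on an actual
  overlapping gene pair.
- The projected frame processes are Markov approximations (quantified
  above).
- Conserved alternative frames are a property of the code and the +1
  constraint; the package makes no claim about biological functionality
  of any particular frame.
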
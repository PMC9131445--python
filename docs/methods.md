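# Methods

## Model and assumptions

The simulator treats a competition assay as three coupled 1:1 mass-action
equilibria-worth of species — free protein P, free labeled ligand (probe)
L, free inhibitor I, and the complexes PL and PI — governed by two
dissociation constants and three conservation laws:

    K_PL = [P][L]/[PL]          P0 = [P] + [PL] + [PI]
    K_PI = [P][I]/[PI]          L0 = [L] + [PL]
                                I0 = [I] + [PI]

Assumptions inherited from this model: complete equilibrium (no kinetics),
exclusive competition for a single shared site (no ternary PLI complex, no
cooperativity or multivalency), ideal solution behavior, and a readout
that maps linearly onto the fraction of probe bound, f = [PL]/L0. Assay
realities outside the model: solubility limits, inner-filter and other
photophysical artifacts, incomplete equilibration, and plate-level noise
(Z′ statistics). Results are therefore upper bounds on what a real
readout can resolve.

## Exact solutions

**Binary system.** Substituting [PL] = p·L0/(K+p) into protein
conservation gives a quadratic in free protein p:
p² + (K + L0 − P0)p − K·P0 = 0. The solver uses the sign-stable branch of
the quadratic formula and derives every other species by mass action
(L0·K/(K+p), p·L0/(K+p)), so no expression subtracts nearly equal
quantities; conservation and mass action hold to machine precision over
the full tested range (totals 1 pM–10 mM, K_D 1 pM–1 mM).

**Ternary system.** The same substitution for both complexes yields the
monic cubic in p with coefficients

    a = K_PL + K_PI + L0 + I0 − P0
    b = K_PL·K_PI + K_PI·(L0 − P0) + K_PL·(I0 − P0)
    c = −K_PL·K_PI·P0

The conservation function g(p) = p + p·L0/(K_PL+p) + p·I0/(K_PI+p) − P0
is strictly increasing on p ≥ 0 with g(0) = −P0 < 0 and g(P0) ≥ 0, so
exactly one cubic root lies in [0, P0]. Selecting that root replaces the
two-branch rule (choose by which affinity is larger) that a
complex-concentration cubic would require; there is no case analysis and
no branch error to make. The coefficient expressions are grouped so that
every floating-point operation is invariant under exchanging the ligand
and inhibitor roles, which makes the L↔I swap symmetry of the solution
bitwise exact.

## Numerical procedure

1. Roots of the cubic via the companion matrix (`numpy.roots`); real
   roots within [0, P0] (small tolerance) are candidates; the one with
   the smallest |g| is kept.
2. Newton polish on g. g' ≥ 1 everywhere, so the iteration is well
   conditioned; g is concave, so after at most one clamped overshoot the
   iterates converge monotonically.
3. Canonicalization: the polished root is snapped to the largest double
   with g(p) ≤ 0. LAPACK eigenvalue output can vary in the last ulp with
   workspace alignment; pinning a canonical representative makes repeated
   solves of the same system bit-identical, which the CLI's
   byte-determinism contract relies on.
4. Residual validation: the reconstructed state must satisfy all three
   conservation laws to relative 1e−9. Free species are computed by mass
   action (L0·K/(K+p)), not subtraction, so ligand and inhibitor balances
   hold to a few ulp by construction and the protein balance is the real
   check.
5. Escalation: if double precision misses the residual bound, the solve
   is repeated by bisection on g in 50-significant-digit arithmetic
   (mpmath) and the result is canonicalized the same way. In practice the
   double path meets the bound across the tested domain; the escalation
   path is exercised directly in the tests.

A failure after escalation raises `NumericalFailure`: it signals a bug,
never an acceptable outcome for valid inputs.

**Independent oracle.** `bisection_oracle` solves the same g by plain
bracketing bisection (`scipy.optimize.bisect`, relative tolerance at the
4-ulp floor, tiny absolute floor so roots far below P0 still converge).
It shares no code with the cubic route and is used throughout the tests
as the dual-route check; agreement is required to relative 1e−8 and is
observed at ~1e−15.

**Degenerate inputs.** P0 = 0 returns the all-free state. I0 = 0 reduces
exactly to the binary solve. L0 = 0 keeps the protein–inhibitor pair
equilibrated (complex_PL = 0 but complex_PI follows the reduced 1:1
problem) — returning an all-zero-complex state there would put a
discontinuity at the sweep boundary.

## Assay construction and metrics

The protein load for a baseline fraction f0 is the closed-form inversion
P0 = f0·L0 + K_PL·f0/(1−f0), valid for 0 < f0 < 1; its round trip through
the binary solver is tested to relative 1e−9. Sensitivity to a compound
is the readout reduction 100·(f0 − f_inh)/f0, identically the percentage
of the readout's dynamic range consumed. An inhibited fraction above the
baseline is rejected as outside the competitive model rather than
clamped.

## Sweeps and the optimum probe affinity

Sweeps move the probe affinity over a uniform pK_D grid and **rederive P0
at every grid point** so the no-inhibitor baseline is constant across the
axis — the constant-baseline design that produces the valley response.
Defaults, chosen as the standard high-throughput screening conditions the
simulations model: L0 = 10 nM (fluorescence detection floor),
I0 = 10 μM (library screening concentration), f0 = 0.7, probe grid
pK_D 4–10 in steps of 0.005, inhibitor pK_D set {5, 6, 7, 8, 9} (10 μM
down to 1 nM K_D — the affinity window a primary screen wants to flag).

The optimum is the grid argmax of the mean deviation f0 − f across the
inhibitor set. Mean (equivalent to sum for a fixed set) is the natural
aggregate when every inhibitor affinity in the window matters equally.
Ties break toward the lower pK_D (the weaker probe is cheaper to bind
with protein). Because the valley floor is nearly flat, the point
estimate is reported together with a plateau: the contiguous grid span
whose objective is within 1% of the maximum. Under the default conditions
the optimum lands at pK_D ≈ 6.97 (≈107 nM K_D) with a plateau spanning
roughly pK_D 6.2–7.8; with an undetectably weak inhibitor the objective
is ≈0 everywhere and the plateau degenerates to a wide, meaningless span.

Grid resolution: halving the step moves the reported optimum by at most
one coarse step (tested); the 0.005 default resolves the optimum well
inside the plateau's flatness.

The lookup table iterates the optimum search over the Cartesian product
of ligand totals, inhibitor totals, and baseline fractions, in that fixed
row order. The optimum pK_D is non-increasing in inhibitor load: with
more competitor present, a weaker probe suffices.

## Serialization and determinism

Sweep output is long-form CSV (ligand_pkd, inhibitor_pkd,
protein_total_molar, fraction_bound) or the same records as JSON, at full
shortest-round-trip float precision with LF endings. Identical
invocations produce byte-identical files (guaranteed by the root
canonicalization above). Note that `pandas.read_csv` must be given
`float_precision="round_trip"` to reproduce the written doubles exactly;
its default parser can be off by one ulp.

## Testing scope

Property tests draw totals from 1 pM–10 mM and K_Ds from 1 pM–1 mM
(log-uniform, derandomized hypothesis profiles); this covers the
concentration regimes of fluorescence-based screening with orders of
magnitude to spare. What passing tests do not show: behavior of real
assays outside the model's assumptions (see above), n:m stoichiometries,
or K_D/concentration scales beyond the tested range.
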
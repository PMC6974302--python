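# Methods

## The model

`chirosim` simulates the joint emergence of biological homochirality and
functional RNA on a two-dimensional mineral-like surface.  The system is an
N x N grid of "rooms" with toroidal topology (indices wrap, so there are no
edge effects).  Molecules interact only with molecules in the same room
within a time step, and may hop to adjacent rooms between steps.

Four molecular species exist:

* **Nucleotide precursors** — chiral raw material (one nucleotide-equivalent
  each) with no base identity, modelled on glyceraldehyde-like compounds
  that racemize readily.  Precursors are the *only* species whose
  handedness can flip (rate `P_CIC`); D- and L-nucleotides never
  interconvert directly.
* **Nucleotides** — a base (A, U, C or G, drawn uniformly at formation) plus
  a handedness.  They form from precursors (`P_NF`, or `P_NFR` under
  synthetase catalysis) and decay back (`P_ND`), keeping their handedness.
* **RNA chains** — ordered runs of (base, handedness) residues.  Chains are
  directionless: the model never invokes 3'/5' polarity, so the two ends
  are interchangeable and sequence recognition also checks the reversed
  residue order.  A 1-residue chain *is* a free nucleotide; the
  implementation keeps a single canonical representation (the nucleotide
  pool) so the two encodings never coexist.
* **Template complexes** — a template chain with substrates (nucleotides or
  oligomers) base-paired onto it at definite positions; the replication
  intermediate.

Every event is an independent Bernoulli trial per eligible entity or site
per step (a synchronous Monte-Carlo step), with probabilities:

| event | rate |
| --- | --- |
| precursor racemization | `P_CIC` |
| nucleotide formation (non-enzymatic / NSR-catalysed) | `P_NF` / `P_NFR` |
| nucleotide decay | `P_ND` |
| chain-end residue decay (single-strand / base-paired end) | `P_NDE` / `P_NDE^(3/2)` |
| backbone bond breaking (single-strand / duplex site) | `P_BB` / `P_BB^(3/2)` |
| duplex separation at r base pairs | `P_SP^((r+1)/2)` |
| substrate attraction onto a template | `P_AT` x `P_FP` per false pair |
| template-directed ligation (non-enzymatic / REP-catalysed) | `P_TL` (x ladder, x `F_CST`) / `P_TLR` |
| surface-mediated ligation | `P_RL` (x ladder, x `F_CSS`) |
| movement of a precursor / nucleotide / m-mer chain | `P_MPN` / `P_MN` / `P_MN/sqrt(m)` |

The 3/2 exponents express the synergy of breaking two parallel bonds (or
losing two paired end residues) at once; the `(r+1)/2` exponent makes long
duplexes progressively harder to melt while crediting single-strand
self-folding with half a pair; the `1/sqrt(m)` follows Zimm scaling of
polymer diffusion.  Interior residues of a chain are protected and never
decay.  Effective rates (probability x multiplier) are clamped to [0, 1];
a clamp triggers a logged warning.

Default parameter values are the package's `Params()` defaults (grid side
20, 50000 precursors, 8 collision rounds, chiral-selection factors 0.5,
catalytic domains GUUCAG for the replicase and ACUGGC for the synthetase).
The two catalytic rates `P_NFR` and `P_TLR` default to **zero**: their
active values (0.2 and 0.9) apply only in scenarios that model the
corresponding ribozyme.

## Chiral selection, cross-inhibition, and the primer effect

Both synthesis routes prefer same-handed monomers: an opposite-handed
incomer joins at a rate damped by `F_CSS` (surface route) or `F_CST`
(template route), with 0 meaning complete selection and 1 none.

**Cross-inhibition** — the termination of elongation after an
opposite-handed residue is incorporated — is encoded *structurally*: a
chain end whose terminal residue differs in handedness from its neighbour
is blocked for extension.  No separate flag is carried, so the property
survives fragmentation consistently: breaking a chain behind the
heterochiral junction exposes a homochiral end that is extendable again,
matching the chemistry of removing the inhibiting residue.  A consequence
worth noting: if an opposite-handed *oligomer* (not monomer) is ligated,
the junction is interior and the new end is not blocked.  The
`no_termination` control variant disables blocking entirely; chimeric
chains then extend freely and the symmetry-breaking disappears.

**The primer effect** — extension being faster than initiation — enters as
length-dependent multipliers (R1, R2, R3, Rn) on the ligation rate, keyed
by the current length of the *extending* polymer (monomer, dimer, trimer,
longer).  Ladders are normalised to R1 = 1, so `P_RL`/`P_TL` is the
initiation rate and Rn the fold-speedup of established-polymer extension;
every ladder used in the study has Rn = R3 (for example
"Rn = R3 = 20 x R2 = 200 x R1" is the tuple (1, 10, 200, 200)).  Separate
ladders apply to the surface and template routes.

## The scheduler

Each step applies a fixed phase order (chemistry before transport;
determinism requires *some* fixed order, and the mirror test covers it):

1. **ribozyme census** — every free chain is checked for the catalytic
   domains; a chain qualifies if it contains the domain as a contiguous
   base run of uniform handedness (either residue order) and is at most
   twice the domain length (longer chains are assumed unable to fold the
   catalytic core).  The census gives per-room, per-handedness *credits*.
2. **precursor events** — racemization, then nucleotide formation.  In a
   room with same-handed NSR credits, precursors use the enzymatic channel
   (`P_NFR`) while credits last, one credit per catalysed formation;
   with no same-handed synthetase present the non-enzymatic `P_NF`
   applies.
3. **nucleotide decay.**
4. **C_T collision rounds** per room: molecules (free chains, complexes,
   free nucleotides) are grouped pairwise uniformly at random (an odd
   molecule idles).  Each pair attempts one of the two collision outcomes:
   if one partner qualifies as a template for the other (the substrate not
   longer than the free template run, and attraction is enabled) the
   attraction branch is taken, otherwise surface ligation; when both are
   possible a fair coin decides.  Attraction is chirality-blind — all
   chiral discrimination happens at ligation — and base-pairing fidelity
   enters as `P_FP` per non-complementary position.  The first substrate
   lands anywhere on a bare template (uniform start); later substrates
   align contiguously beside the block on a uniformly chosen fitting side,
   so each complex hosts one growing region.  Molecules absorbed into a
   complex are excluded from later rounds; newly formed chains and
   complexes participate in them.
5. **template-directed ligation** at every junction between adjacent
   substrates.  The longer attachment is the growing chain (ties random);
   its junction end must not be blocked.  If template, both substrates and
   an available same-handed replicase agree in handedness the ligation
   fires at `P_TLR` and consumes one REP credit; otherwise the
   non-enzymatic rate `P_TL x ladder x (1 or F_CST)` applies.  Ligated
   substrates are represented merged into a single attachment.
6. **degradation** — chain-end decay and bond breaking, free chains first,
   then complexes.  A duplex-region bond break severs a complex into two
   smaller complexes, preserving local pairing; a single-strand template
   break splits the template and each attachment follows its side.  The
   synergistic paired-end decay applies only where a template terminus is
   paired with an attachment terminus; an attachment end whose template
   partner is chain-interior does not decay (interior residues are
   protected, and the two-residue event needs both partners to be ends).
7. **duplex separation** — with probability `P_SP^((r+1)/2)` all strands of
   a complex return to the room as free molecules.
8. **movement** — per-molecule Bernoulli hops to a uniformly chosen
   adjacent room (4-neighbour von Neumann by default; an 8-neighbour Moore
   variant is a configuration switch).  A complex moves as one unit with
   mass equal to its total residue count.

A template must be an actual chain (length >= 2): a lone nucleotide does
not template another monomer.  A single base pair in solution is not a
replication intermediate, and admitting it would let transient 1-bp
"duplexes" sequester most of the monomer pool at the default `P_AT`.

## Randomness and reproducibility

One seeded PCG64 generator drives every phase in a fixed order; runs are
bit-reproducible from the seed, and the compiled kernels draw from the same
stream as the python layer.  Per-entity Bernoulli batches are drawn as
exact binomials (chunked CDF inversion, so the pmf(0) term cannot
underflow) and the affected individuals are then selected without
replacement — the exact conditional distribution of the underlying
independent trials.  Three deliberate, documented truncations of order
p^2 exist, all far below statistical resolution at study rates:

* in a room containing only free nucleotides and a small monomer ligation
  rate (`P_RL*R1 < 1e-3`), the C_T rounds' ligation candidates are drawn
  as one binomial; a fired candidate's dimer does not take part in the
  remainder of that room-step (at `P_RL*R1 ~ 1e-6` a candidate fires in
  ~4e-5 of room-steps at all);
* complex-degradation events are detected per site in the compiled pass
  and applied by the python layer; at most one event per complex per step
  is honoured (two events on one complex in one step has probability
  ~(L*P_BB + 2*P_NDE)^2 ~ 1e-8);
* engine strands are capped at 512 residues.  The cap is unreachable in
  practice (a chain of that length carries enough breakable bonds that its
  expected lifetime is far below the time needed to grow it); exceeding it
  raises an error rather than silently altering the dynamics.

## Mirror symmetry by construction

Every rate in the model is handedness-symmetric.  The engine exploits
this: it operates on two anonymous chirality slots, and the D/L labels are
attached only at configuration (which handedness is inoculated) and at
observation.  `mirror_config` flips the label map and the inoculated
handedness; the mirrored run then consumes the *identical* random stream
and its ee series is exactly the negation of the original's.  The test
suite asserts this bit-exactly; it guards against any rule accidentally
keying on the label rather than the slot.

## Observables

The headline statistic is the enantiomeric excess ee = (D - L)/(D + L)
counted over *all* chiral material: precursors, free nucleotides and every
chain residue including those inside complexes.  Records further carry
per-handedness totals, chain-length histograms (free nucleotides count as
1-mers; template and attachments count as chains of their own lengths;
lengths above 20 share an overflow bin, matching the display convention of
the study's figures) and active ribozyme counts.  Chimeric chains are
binned by majority handedness, ties resolved by the first residue — a
slot-based rule, hence mirror-consistent.  Trajectories and per-molecule
snapshots are plain TSV; run configurations are KEY=VALUE text.

## Scenarios and the reduced scale

`chirosim.experiments` provides the named study conditions: the
template-directed family (inoculation of 50 D 6-mers, `P_TL` = 0.01,
`P_RL` = 0, chiral selection complete/partial/absent plus the
no-termination control), de novo appearance of RNA, the surface-only
primer-ladder family (`P_AT` = 0, `P_NDE` = 1e-5, ladders uniform to
1:10:200), and the ribozyme-emergence settings (moderate ladders with one
catalytic rate active).  Full-scale presets keep the printed grid (N = 20,
T_NPB = 50000); their horizons are millions of steps (3e6 for the
non-ribozyme scenarios, 6e6 for ribozyme emergence, which is documented to
unfold on that timescale).  These are *documented slow runs*, not test
gates.

Every scenario has a `_reduced` variant for desk-scale work: N = 10,
T_NPB = 2000, 2e5 steps, inoculations at step 5e4, with **all
probabilities, factors and ladders unchanged**.  The reduced scale keeps
the per-room occupancy of the full system (~5 molecules per room) while
shrinking the population 25-fold and the horizon 15- to 30-fold; each run
completes in well under a minute.  What the reduced runs demonstrate is
the *direction* of each regime (null controls stay racemic; symmetry
breaking occurs and is strictly bounded away from |ee| = 1; the strong
primer ladder separates from its uniform control).  They do not reproduce
the full-scale magnitudes or waiting times — in particular, spontaneous
ribozyme emergence is a rare event on the reduced horizon, so the
catalytic machinery is exercised by inoculating domain-carrying chains
instead.

## What the generator emulates, and what it does not

All inputs are generated internally: a racemic precursor pool placed
uniformly at random, plus optional homochiral oligomer inoculations
(random or explicit sequences).  This captures the study's initial
conditions exactly, but — like the model itself — abstracts away real
chemistry: no thermodynamics or energy balance (all events are fixed
per-step probabilities), no secondary structure (function is assigned by
sequence lookup), no wobble pairing (fidelity is the lumped `P_FP`), and
no explicit mineral geometry (the 2-D grid itself is the surface).
Passing tests therefore validate the model's internal logic and its
qualitative regime structure, not quantitative agreement with laboratory
kinetics.

## Known limitations

* The collision-outcome rule (attraction preferred when only one branch
  qualifies, coin flip when both do) is one concrete reading of "one of
  the two events may occur"; regime results are not sensitive to it, but
  other tie-breaks are conceivable.
* When attraction is disabled (`P_AT` = 0) the attraction branch is
  treated as non-existent rather than as an always-failing attempt, so
  template-qualifying pairs ligate at the full surface rate.
* Whether a ribozyme-qualifying chain may simultaneously serve as template
  or substrate in the same step is left permissive (it may), and a domain
  match is only required to be uniform-handed inside the matched window.
* The strand-length cap and attachment-count caps are implementation
  bounds with explicit error reporting, not model features.
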
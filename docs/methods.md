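# Methods

## The machine model

The substrate is a concatenative stack language over a 29-character
alphabet. Values are strings; a program is any string over the alphabet, so
the canonical length-then-lexicographic Gödel numbering is bijective base-29
numeration (`""` ↔ 0). The choice of machine is an implementation decision:
any Turing-complete model with a bijective numbering, effective composition,
effective s-m-n and a step-counted interpreter would do. A concatenative
language was chosen because the two effective operations the model leans on
are structurally trivial there — composition is concatenation (with a no-op
separator so adjacent literal runs do not merge), and partial application is
"prepend a quoted literal".

Three design points deserve explanation:

- **Phenotypes are self-reproducing programs.** A maximal run of data
  characters is a single push-literal instruction, so the token `t3:+`,
  executed as code, rebuilds itself: `ϕ_q(s) = q`. This is what makes the
  two-stage σ semantics compose cleanly — the output of a gene's
  self-assembly is itself runnable "digitized material".
- **The negator `~N` and the liar guard.** `~` flips the polarity suffix of
  the top value; `N` inspects the current frame's *own input* and, iff that
  input carries the negation marker `N`, re-invokes it on itself. Hence for
  a conflicted code `g¬ = g·"."·"~N"`:
  `ϕ_{g¬}(y)` halts with `q¬` for every benign input `y` (attacks succeed,
  negative-selection simulations of `σ(g¬, g)` halt and expose the negated
  phenotype), while `ϕ_{g¬}(g¬)` recurses forever — the forbidden codes are
  exactly the codes with non-halting self-application, and the Gödel
  sentence `σ(g¬, g¬)` exhausts any budget. This conditional
  self-re-invocation is the contract that makes the fixed point's two legs
  "undefined on both sides"; an encoding in which the sentence halted would
  be wrong.
- **Sentinel machines.** Finite membership machines (`D…EBH` chains ending
  in a loop) realize the listable sets: a sentinel halts exactly on its
  member texts. The genome set G and the registry set G¬ are represented by
  sentinels, so "W of an index" has a concrete program behind it.

Halting is undecidable, so *halts* always means *halts within the step
budget* `T` (default 10,000; every report records it), and extensional
equality of programs always means agreement of (status, output) on a
declared finite battery at budget `T` — by default the 50 state tokens
`s0..s49`. One interpreter transition is one step, nested applied code
included, which keeps dovetailing fair.

## Recursion-theoretic constructions

- `σ(x, y)` is the code `lit(y)·lit(x)·"!!"`: push both texts, call x on y,
  call the result on the state input. It exists for all pairs, is injective
  (textually and through the Cantor composite `pair(x, y)`), and its
  execution is validated against an independent two-stage oracle that shares
  no code with the construction. Because the σ program replays both stages
  inline plus ~8 bookkeeping steps, soundness checks give it `2T + 16` steps
  against `T` per oracle stage; all pool programs halt far below `T` or not
  at all, so statuses agree.
- The Rogers fixed point of a total transformer `f` is `v = σ(e, e)` where
  `e` computes `x ↦ f(text of σ(x, x))` (built with the quoting instruction
  `Q`). Both `ϕ_v` and `ϕ_{f(v)}` then literally execute the same derived
  code, so the law holds extensionally (indeed intensionally at stage 2).
  Note that the *guarded* negator `~N` is not a lawful fixed-point
  transformer: it is total on the state battery but intentionally diverges
  on negator-marked code inputs — that divergence is its liar property.
  Fixed-point checks therefore draw transformers from compositions of
  `{identity, no-op, plain flip, pad, duplicate}`, which are total on all
  strings.
- `enumerate_we` is a bounded dovetail: candidate i enters at round i+1,
  every active candidate advances one 64-step quantum per round, candidates
  are swept in ascending order, and a candidate retires on halting (becoming
  a member, in discovery order) or on exhausting the per-candidate budget.
  Members are monotone in the bound (prefix property) and re-verifiable by a
  direct run. Both the candidate universe (`max_candidates`, default 256)
  and the per-candidate budget are explicit surrogate bounds: gene and
  sentence Gödel numbers are astronomically large (≈ 29^len), so a
  feasible enumeration cannot reach them from 0. For this reason every
  productivity check pairs the first-N-enumerated-members exclusion with
  the strictly stronger direct exclusion from the exact finite sets
  (gene gns, registry sentence gns, stock antibody gns).

## The synthetic world

Gene i is the program `t{i}:+` plus 0–8 seed-dependent no-op paddings
(distinct Gödel numbers across seeds, and a nontrivial code space for
V(D)J); tissues are distinct by construction. Defaults: 8 genes, one attack
at step 1 on gene index 1, transformer pool = the attacking antigen's code,
vdj_n = 500, T = 10,000, enumeration bound N = 10,000, seed 42. All genes
are mirrored by default (AIRE-dropout scenarios remove a configured tissue).
Antigens are `~N` plus 0–5 paddings.

What the generator emulates: a finite world of halting, tissue-specific,
polarity-positive self-assembly codes, attacked by total polarity-inverting
transformers. What it does not emulate: nucleotide/protein sequences,
junctional V(D)J diversity, clonal expansion, affinity maturation,
inflammation dynamics, population dynamics. A green test therefore
establishes the *logical* architecture — mirror, selection, fixed-point
rendezvous, productive novelty — not any quantitative immunological rate.
The empirical "only ~5% of thymocytes are released" figure is a reported
observation, not a model rule; the release fraction here is whatever the
filters produce (with one negator per pool: generated/3 motifs are
diagonal, ≈ 33% of the post-positive stage).

## Selection and response rules

- V(D)J samples uniformly over form × transformer × gene via per-epoch
  shuffles; any n at least the size of the space covers it exhaustively.
  Transformers are never applied to non-gene codes. A transformer acting
  extensionally as the identity on its gene degenerates the motif to SELF
  (decided by the battery check), removed at positive selection.
- Negative selection simulates motif action instead of scoring affinity:
  reactivity is a computation. The elimination rule is literal — a halting
  simulated outcome that negates the recorded phenotype eliminates the
  motif. With negator pools this releases exactly the diagonal motifs. A
  non-negating, non-identity transformer (e.g. one padding the output
  token) would leave a halting program-change motif in the released set;
  the rule as stated does not cover that case and scenario pools avoid it.
- Diagonal motifs whose simulation diverges at budget (the liar property)
  are retained: divergence is not negation of a record. This is an
  interpretive choice; the alternative (rejecting on divergence) would
  empty the released repertoire of precisely the motifs detection needs.
- Detection is intensional: exact equality of composite integers between a
  released motif and an updated peripheral index, never battery equality,
  and a benign `σ(g, g)` index never fires.
- The decision table resolves in this order: attack on an undeveloped
  tissue → UNDETECTED; registry-listed sentence → KNOWN_ANTIBODY (stock
  antibody, the antigen's own involutive code); rendezvous match on a novel
  sentence → NOVEL_ANTIBODY (produced, applied, then registered, so a
  re-attack takes the known path); attack without rendezvous →
  CYTOKINE_STORM, modeled minimally as "damage sensed, no code-specific
  response, phenotype not restored"; no attack but a patrolling released
  motif negates a healthy tissue → AUTOIMMUNE; otherwise BENIGN (a kind
  added so the no-attack scenario has a reportable outcome). Patrol
  executions are deterministic and therefore cached across patrol steps.
- The simulator stops at outcome classification: it does not resolve who
  "wins" the undecidable contest at the fixed point.

## Scenario runner

`baseline_novel` guarantees the needed diagonal motif by appending it
deterministically if sampling missed it (flagged `rescued` in the report);
`--no-rescue` exposes the stochastic-miss case, observable when vdj_n is
below the combination space. `forced_escape` injects one `σ(g¬, g)` motif
into the released set (flagged `injected`). Reports (summary JSON, JSONL
events, TSV repertoire) contain no timestamps and serialize with sorted
keys, so equal seeds give byte-identical files. Derived seeds are
`seed`, `seed+1` (V(D)J), `seed+2` (antigen).

## Numerical / degenerate-input choices

- Stack underflow pops the empty string; applying a non-code value as code
  leaves the argument unchanged; a dangling quote is a no-op. Every string
  is a valid program, which keeps the numbering total.
- Budget exhaustion reports steps = T and no output; halting reports the
  exact step count, invariant under budget increase.
- Enumeration defaults (`enum_budget` 256 steps/candidate) reflect that
  sentinel members halt within ~4·|members|+2 steps and non-members loop;
  raising the budget cannot add members for sentinel-type indexes.

## Known limitations

- Totality, halting-set membership, and extensional equality are all
  budget-and-battery surrogates of undecidable properties; results are
  claims at the recorded T and battery only.
- The unbounded creative/productive set theory is represented only by
  bounded prefixes; the claim "the sentence index lies outside *all*
  enumerations" is untestable and is not asserted.
- The mirror-neuron instantiation of the same machinery (replace gene codes
  by action codes) is structurally identical and is not separately
  implemented.
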
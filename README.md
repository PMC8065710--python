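# gtais — Gödel–Turing–Post artificial immune system simulator

`gtais` is an executable model of adaptive-immune self/non-self
discrimination built from recursion theory rather than from affinity scores.
It is aimed at researchers in theoretical/computational immunology and
artificial immune systems who want the Gödel–Turing–Post (G-T-P) account of
thymic selection and antigen detection as a concrete, testable program: every
claim about self-representation, receptor selection, fixed points, and
novelty production is realized on an actual machine model and checked by
property tests.

## The model

All biotic entities are programs over a tiny concatenative stack language
with a bijective Gödel numbering (program text ↔ non-negative integer `gn`,
length-then-lexicographic). The world is built from four pieces:

- **Self-Ref (Diag).** A gene is a program `g` whose self-application
  `Diag(g) = ϕ_g(g)` halts and emits a tissue-labeled phenotype `q` of
  positive polarity (token `t3:+`). The set **G** of such genes are the
  "theorems" of the genomic formal system; their developed phenotypes are the
  benign world state.
- **Self-Rep (σ).** The s-m-n substitution index `σ(x, y)` names the offline
  program simulating the two-stage online execution
  `ϕ_{σ(x,y)}(s) ≅ ϕ_{ϕ_x(y)}(s)`. The thymic mirror holds `σ(g, g)` plus
  the recorded phenotype for every mirrored gene (AIRE dropout removes
  records). `σ(x, y)` exists for every pair, even divergent ones.
- **Negator antigens.** An antigen is a total transformer `f¬` with
  `ϕ_{f¬∘g}(y) = ¬ϕ_{ϕ_g(g)}(y) = q¬` — it inverts the phenotype polarity,
  never the tissue. Negation is an involution. The conflicted code
  `g¬ = f¬∘g` is a *forbidden* code: its own self-application diverges
  (`ϕ_{g¬}(g¬)↑`), because the negator re-invokes negation-marked inputs on
  themselves.
- **V(D)J and selection.** The thymus generates receptor motifs
  `σ(g, f∘g)`, `σ(f∘g, g)`, `σ(f∘g, f∘g)` over a transformer pool. Positive
  selection rejects input-change and self motifs; negative selection *runs*
  each program-change motif against the mirror records and eliminates those
  whose outcome negates a recorded phenotype (the autoimmune-capable ones).
  Only diagonal motifs `σ(f∘g, f∘g)` survive full training.

Detection is a fixed point ("Gödel sentence"): when `f¬` attacks gene `g`
online and the IFN-γ circuitry is intact, the peripheral MHC index for that
tissue is updated from its benign default `σ(g, g)` to `σ(g¬, g¬)` — exactly
the composite index of the surviving diagonal motif for that antigen–gene
pair. An exact integer match between a released motif and an updated
peripheral index is the rendezvous by which a self-code self-reports that it
is under attack. Detection of a *novel* sentence triggers the productive
response of Post: a fresh antibody code whose `gn` lies outside the
enumerated surrogates of the known genomic and forbidden sets and whose
application (negation being an involution) restores the attacked tissue.
Knockouts break the chain in characteristic ways: IFN-γ off ⇒ no peripheral
update ⇒ cytokine storm (damage sensed, nothing restored); AIRE dropout ⇒
untestable `σ(g¬, g)` motifs escape negative selection ⇒ autoimmunity.

## Worked example

```
$ gtais run --scenario baseline_novel --seed 42 --out out/
scenario : baseline_novel
outcome  : NOVEL_ANTIBODY
counts   : {'generated': 500, 'post_positive': 333, 'released': 166}
antibody : gn=6
```

Reading: from 500 V(D)J motifs over an 8-gene genome and one negator
antigen, positive selection removed the 167 input-change motifs, negative
selection eliminated the 166 program-change motifs that provably negate a
mirrored phenotype, and 166 diagonal motifs were released. The attack on
tissue `t1` flipped its phenotype to `t1:-`; with IFN-γ on, the peripheral
index update matched a released diagonal motif and a novel antibody (the
minimal polarity-flip code, `gn=6`, outside both enumerated known sets) was
produced and restored `t1:+`. The written `summary.json`, `events.jsonl`
and `repertoire.tsv` are byte-stable for equal seeds. Other scenarios:
`known_antigen`, `ifn_knockout`, `aire_knockout`, `forced_escape`,
`no_attack`; `gtais selftest` runs a quick invariant battery.

## Acceptance script

```sh
python scripts/acceptance.py --seed 42 --out results/acceptance.json
```

recomputes the entire scenario suite from scratch at the given seed —
synthetic genome, thymic training, attack, detection, response — prints the
outcome table with per-stage repertoire counts, and writes the results JSON.

## Layout

- `src/gtais/machine_core.py` — language, interpreter, Gödel numbering,
  composition, pairing, bounded totality.
- `src/gtais/recursion_theory.py` — σ (s-m-n), Diag, Rogers fixed point,
  bounded dovetail enumeration of W-sets, liar fixed point.
- `src/gtais/immune_world.py` — synthetic genomes, negator antigens,
  sentinel machines, known-antigen registry.
- `src/gtais/thymus.py` — Self-Rep records, V(D)J generation,
  positive/negative selection.
- `src/gtais/periphery.py` — attacks, P-MHC updates, rendezvous detection,
  antibody production, patrol, response classification.
- `src/gtais/scenarios.py`, `src/gtais/cli.py` — scenario runner and the
  `gtais` command.

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
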
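# dsrloops

Find the positive feedback loops of a biochemical reaction network that can
actually drive multistationarity — as opposed to the (usually many) positive
loops that cannot.

Positive feedback is necessary for a reaction network to admit multiple
positive steady states, but most networks contain several positive loops and
only some of them matter. `dsrloops` implements an exact, parameter-free
procedure that singles out the relevant ones:

1. Build the stoichiometric matrix `A` (exact integer arithmetic, exact
   rank `s`) and the influence matrix `Z` — the sign pattern of the rate
   Jacobian, either supplied as a `+/-/0` table or derived from mass-action
   monotonicity.
2. Expand the **injectivity polynomial**: the determinant of `A @ Z^T` with
   the rows indexed by the pivots of the reduced conservation-law basis
   replaced by those basis vectors. If the polynomial is nonzero and
   single-signed, the network is injective on every positive compatibility
   class and **cannot** be multistationary.
3. Select the terms with the *wrong sign* `(-1)**(s+1)`, realize each one as
   the 2s-nuclei of the signed DSR graph (the bipartite species/reaction
   digraph), keep the wrong-sign nuclei, and report the positive circuits
   they contain. Breaking all of these loops removes every wrong-sign term
   and with it the possibility of multiple steady states.

All arithmetic on the polynomial path is exact (integers / rationals); no
floating point is involved anywhere, so term signs — the entire output —
are never subject to rounding.

## Input formats

Reaction lists are plain text, `#` comments and blank lines ignored:

```
r1: Xcyt -> Xnuc
r2: Xnuc -> Xcyt
r3: Xnuc -> Xnucp      # species order = first appearance
r4: Xnucp -> Xnuc
r5: A <-> B            # expands to r5_f / r5_r
r6: C8 -> 0            # "0" is an empty side (outflow/inflow)
r7: 2 A + B -> C       # integer coefficients, whitespace-separated
```

Influence tables are TSV with a header of reaction ids and one row per
species, cells in `+`, `-`, `0`; rows/columns are matched by name:

```
species	r1	r2	r3	r4
Xcyt	+	0	0	0
Xnuc	0	+	+	0
Xnucp	0	0	+	+
```

## Command line

```sh
dsrloops analyze network.rxn --mass-action                 # mass-action signs
dsrloops analyze network.rxn --influence signs.tsv         # explicit signs
dsrloops analyze --fixture mitosis_z1 --format json        # bundled example
dsrloops analyze --fixture apoptosis --all-loops           # list every positive loop
dsrloops polynomial --fixture mitosis_z1                   # just the polynomial
dsrloops graph --fixture mitosis_z1 --out dsr.dot          # DOT export
dsrloops fixtures                                          # list bundled models
```

Exit codes: `0` success, `2` network/input errors, `3` influence errors.

Bundled fixtures (`dsrloops.fixtures.get_fixture`): the mitosis-onset toy
model with two influence variants (`mitosis_z1`, `mitosis_z2`), the
Ring1B/Bmi1 `ubiquitination` model, the `phospho_two_site` cycle, the
`cascade_2layer` cascade with explicit feedback, the `apoptosis`
caspase-activation model and the bare `michaelis_menten` mechanism.

## Library use

```python
from dsrloops import find_relevant_loops, get_fixture

fx = get_fixture("mitosis_z1")
report = find_relevant_loops(fx.network, fx.influence)
print(report.verdict)                 # INCONCLUSIVE
for loop in report.relevant_loops:
    print(report._loop_line(loop))    # r3 -> Xnucp -> r3   signature (+,+)
print(report.to_json())
```

The determinant expansion is cross-checked by an independent route that
sums signed nucleus labels over the DSR graph (`nucleus_expansion`); the
test suite additionally verifies both against a brute-force permutation-sum
determinant.

## Tests and acceptance report

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the measured target quantities from
scratch by running the package on the bundled inputs and writes them as
JSON (`{"<target id>": {"value": ..., "n": ...}}`).
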
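# The fepout text dialect

`hcnfep` reads and writes per-window alchemical energy-difference samples
in a small line-oriented text dialect. The engine-native FEP output formats
vary in layout and carry much that this analysis never uses, so the package
defines its own minimal contract and ships both a parser
(`hcnfep.fep_io.parse_fepout`) and a writer (`hcnfep.fep_io.write_fepout`);
the pair is round-trip tested bit-for-bit.

## Grammar

```
file        := line*
line        := comment | window-head | equil-mark | sample
comment     := "#" <anything not starting with WINDOW/EQUIL_END>
window-head := "#WINDOW" index lambda_start lambda_end leg
equil-mark  := "#EQUIL_END"
sample      := step delta_u
```

* `index` — 1-based window index.
* `lambda_start`, `lambda_end` — the λ pair of the window; forward windows
  run low→high, backward windows high→low. Legs are matched by the
  (unordered) λ pair, so forward and backward sections may appear in one
  file in any order, or live in two separate files.
* `leg` — `forward` (annihilation) or `backward` (re-coupling).
* `step` — integer or float sample time/step label (not interpreted).
* `delta_u` — the ΔU sample in kcal/mol. No unit conversion is performed.

Samples belong to the most recent `#WINDOW` header. Everything before a
window's `#EQUIL_END` marker is the alchemical-equilibration span: excluded
from `delta_u` by default and reported in `n_equilibration_discarded`
(`include_equilibration=True` restores it). Without a marker the whole
window is production.

## Errors

* malformed header or sample line → parse error naming the line number;
* a window with no production samples → error;
* per-leg window count differing from the declared λ schedule →
  schedule-mismatch error.

## Example

```
# fepout dialect v1; energies kcal/mol
#WINDOW 1 0 0.05 forward
0 0.412
1 0.398
#EQUIL_END
2 0.377
3 0.401
#WINDOW 1 0.05 0 backward
0 -0.388
1 -0.413
```
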
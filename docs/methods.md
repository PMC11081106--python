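# Methods

## Scope and model

`idpcalc` converts single-conformer all-atom PDB structures of disordered
proteins into per-conformer predictions of four experimental datatypes. The
underlying physical models are deliberately minimal — each observable is a
closed-form function of the coordinates of a handful of named atoms:

| datatype | model | output |
|---|---|---|
| pre | Euclidean distance between two template atoms | Å |
| noe | power mean over assignment-combination distances | Å |
| jc  | Karplus curve on backbone φ | Hz |
| smfret | Förster sigmoid on a dye-corrected CA–CA distance | efficiency in (0, 1] |

Two simplifications are inherited from this distance-only treatment and worth
stating: PRE is reported as a plain distance (no intensity-ratio or Γ₂-rate
conversion), and neither PRE nor NOE accounts for the dynamics of the
interatomic vector, which for exchanging ensembles can understate the sampled
distance range. Ensemble averaging and reweighting are explicitly downstream:
the engine emits one value per conformer per restraint.

## NOE averaging modes

An ambiguous NOE row lists a primary atom name plus alternatives on each
side. The engine resolves every name (pseudoatom group names such as `HB`
expand to the `HB1/HB2/HB3` protons actually present), forms the Cartesian
product of the two resolved sets, de-duplicates, and averages the
combination distances `d_k`:

* `r6` (default): `d = ((1/N) Σ d_k⁶)^(1/6)` — the arithmetic power mean of
  exponent +6.
* `rminus6`: `d = ((1/N) Σ d_k⁻⁶)^(−1/6)` — the conventional NOE average,
  dominated by the shortest contact.

Both are means of order ±6, hence bounded by `[min d_k, max d_k]`,
permutation-invariant, and exactly equal to the single distance when N = 1
(the N = 1 case is short-circuited so the reduction is bit-exact). The two
conventions differ materially for uneven combinations, which is why the mode
is an explicit flag rather than a silent default. When a pseudoatom group
expands, the effective N is the product of resolved-atom-set sizes, which
can exceed the count implied by the listed names alone.

## Karplus couplings

`J(φ) = A·cos²(φ − π/3) + B·cos(φ − π/3) + C` with defaults
`A = 6.51, B = −1.76, C = 1.60 Hz` — a standard 3J(HN,HA) parameterization —
overridable per run (`--karplus A,B,C`). φ is the dihedral
`C(i−1)–N(i)–CA(i)–C(i)` in radians internally, range (−π, π], computed with
the atan2 formulation (IUPAC sign convention: clockwise positive viewed along
the central bond). φ is undefined at the first residue; templates naming it
are rejected at parse time, and a missing backbone atom raises (or yields a
null under the `null` policy). The `--degrees` flag affects only how torsions
appear in log output; stored values are never angles.

## smFRET dye correction

The labelled residues' CA–CA distance `D` is stretched by `(n + 7)/n`,
`n = |res1 − res2|`, before the Förster sigmoid `E = 1/(1 + (D′/S)⁶)`. The
`+7` residue offset is a fixed heuristic for dye-linker size (exposed as
`DYE_LINKER_OFFSET`; its provenance is conventional rather than derived), and
`S` is the per-pair scale factor carried by the template, encoding the
experimental dye pair's Förster radius. E is strictly decreasing in D and
confined to (0, 1].

## PDB conventions

Parsing is Biopython's `PDBParser` plus single-conformer semantics: one
conformer per file; multi-MODEL files contribute MODEL 1 only (warning);
altlocs other than blank/'A' are dropped (logged); one chain is retained —
the first encountered, or `--chain`. Author residue numbering is used
verbatim to match template residue numbers; units are Å throughout. Atom
lookups try the exact name, then a proton-dialect fallback (H↔HN, ±1
numbering shifts within 1–3 for numbered protons), logging any substitution.
Pseudoatom expansion applies only to NOE assignment resolution, never to
single-atom lookups. Structures lacking hydrogens surface missing-atom
errors; the caller chooses between aborting (`fail`, default) and recording
`null` for that row/conformer (`null`).

## Synthetic conformers

The generator builds peptides by sequential internal-coordinate placement
(each atom from a bond length, bond angle and torsion relative to three
placed atoms) with idealized backbone geometry (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å; angles 111.0°/116.2°/121.7°), amide H, HA and a CB stub — the
atoms templates can name. Defaults emulate a generic coil pool: a 12-residue
proline-free sequence, φ drawn uniformly from (−170°, −50°), ψ from
(−180°, 180°), ω fixed trans. This emulates the *geometry* of a disordered
pool — known torsions, file-per-conformer layout, realistic atom naming —
but not its physics: no side chains beyond CB, no clash avoidance, no
residue-specific torsion propensities. Tests passing on these fixtures
therefore validate the calculators and pipeline plumbing, not the realism of
any particular ensemble. Generation is deterministic per seed and filenames
are zero-padded so lexicographic and numeric order coincide.

## Numerical choices

* Torsion closure: builder-set φ is recovered by the analyzer to machine
  precision (~1e-15 rad) on in-memory conformers; PDB files quantize
  coordinates to 3 decimals, so disk round-trips agree to ~1e-3 rad.
* Dihedral degeneracy: collinear triples (cross-product norm < 1e-10) raise
  rather than return an arbitrary angle; −π maps to +π to keep the half-open
  range.
* Results JSON stores floats rounded to 4 decimals — ~5e-5 worst-case
  round-trip error, well inside experimental uncertainty for all four
  datatypes.
* Parallelism is over conformers (they are independent); results are
  gathered with order-preserving `Pool.map`, so output files are a pure
  function of inputs and byte-identical for any worker count.
* Summary statistics use the population SD (ddof = 0) over non-null values;
  range membership counts inclusive bounds.

## Design decisions that were genuinely open

* Template column schemas are the minimal sets each equation needs
  (`pre: res1,atom1,res2,atom2`; `noe` adds per-side
  `*_multiple_assignments` cells, space- or semicolon-separated;
  `jc: resnum`; `smfret: res1,res2,scale`). Extra columns are preserved in
  the JSON `"format"` echo but never interpreted.
* Both NOE averaging conventions are first-class because the d⁶ and d⁻⁶
  readings disagree exactly when ambiguity matters.
* "Fraction of conformers within the experimental range" is this package's
  agreement statistic for QC; it is monotone under range widening and easy
  to read restraint-by-restraint.

## Limitations

Distance-only PRE/NOE (no relaxation model), CA-level smFRET (no explicit
dye ensemble or lifetime model), no mmCIF input, no hydrogen building or
structure repair, and no reweighting — the output JSON is designed to feed
such tools, not replace them. The external back-calculator registry defines
the plug-in contract only; no third-party wrappers ship with the package.
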
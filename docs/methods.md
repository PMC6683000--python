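# Methods

## The model

An acquisition file's metadata is modeled as a fixed header — file name,
acquisition timestamp, a flat sample-information map — followed by an
ordered list of instrument modules (MS, LC, or other), each carrying a
model designation, an optional verbatim method string, and a nested
parameter tree of string keys over scalar leaves (string, integer,
decimal, boolean, null). The tree deliberately abstracts over
instrument-class-specific layouts: readers for different source formats
produce the same structure, and reporting addresses parameters by path
rather than by vendor API.

The central operation is the reduction of a collection to its minimal set
of *parameter groups*: maximal sets of files whose metadata is identical
after removal of the per-file fields. Two files belong together exactly
when their merged, stripped parameter trees are content-equal; equality is
decided by a SHA-256 digest over a canonical serialization. Minimality
follows directly: groups carry pairwise distinct trees, and the
`diff_groups` walk reports precisely the paths on which any two groups
differ — which is the operational definition of parameter drift detection.

### Canonicalization

Canonical serialization sorts sibling keys at every level (after Unicode
NFC normalization, by code point), renders scalars by a fixed rule —
integers as decimal text, booleans as `true`/`false`, null as `null`,
strings JSON-quoted (so delimiter characters cannot make distinct trees
alias), decimals by their **preserved source text** — and tags each leaf
with its type, keeping the string `"1"`, the integer `1` and the decimal
`1.0` distinct. Preserving decimal source text (`SourceFloat`, a `float`
subclass remembering its literal) makes hashing reproducible across
platforms and makes the native-JSON writer byte-stable; it also means
`35.0` and `35.00` are *different* settings, which is intended — vendor
formatting is part of the recorded method, and guessing numeric intent
risks merging genuinely different methods. No case folding is applied:
differently-cased vendor labels are not assumed equivalent.

Strict equality is the grouping contract; tolerance-based grouping
(treating near-equal gradients as equal) is out of scope by design, since
the hash key admits no useful notion of "almost".

### What counts as file-specific

Stripping removes the header fields (file name, timestamp, sample info)
and any tree path in a user-extensible exclusion list (`--exclude-path`,
config key `exclude_paths`) — instrument logs can embed per-run timestamps
that no fixed list anticipates. Whether sample information should ever
participate in grouping is genuinely open; it is excluded here because it
varies per file in any real series, and the exclusion list makes the
choice reversible. Each instrument's subtree additionally gains
`Model`/`ModuleType`/`MethodText` leaves so instrument identity and
verbatim method differences participate in grouping and can be cited in
reports; a parameter key colliding with one of these reserved names is a
structural error rather than a silent overwrite. Duplicate instrument
models merge under `#2`, `#3`… suffixes; duplicate sibling keys in any
input are rejected outright — silently dropping a parameter would defeat
the tool's purpose.

## LC method parsing

EASY-nLC-class instruments store the gradient program as free text. The
real vendor formatting is not publicly documented, so the parser defines
an explicit line dialect — `Sample pickup: <v> µl`, `Equilibration:
<v> µl`, a `Gradient:` header followed by `time / duration / flow / %B`
rows — with a registry (`lc_dialect`) for plugging in real vendor dialects
per instrument model later. Parsing is strict where it matters: a gradient
row that fails numeric parse raises with its line number, decimal commas
are rejected (a silent 10× misreading of a flow rate is worse than a
refusal), step times must increase strictly from 0 and %B must lie in
[0, 100]. Unrecognized lines are preserved verbatim in the parameter tree;
a wholly unparseable method logs a warning and leaves the instrument
unchanged, so one bad method cannot abort grouping a 300-file collection.
Parsed gradients attach under a `Gradient` subtree with zero-padded step
indices, making a changed %B step exactly as group-splitting as any MS
setting.

## Ingestion

The native JSON dialect (schema in `data/native_metadata.schema.json`) is
the open per-file interchange format; reading validates structure with
JSON-pointer error paths, rejects duplicate object keys, and preserves
decimal literals. mzML ingestion parses only the header sections
(instrument configurations, referenceable param groups, sample, run
attributes) with an event-driven XML walk that stops at the spectrum list
— spectra are never touched, and the indexed wrapper is transparent. CV
parameters become leaves keyed by term *name* with the accession retained
as a `<name>@accession` sibling: reports need human-readable names,
accessions preserve identity. Component elements map to
`Source`/`Analyzer`/`Detector` subtrees. mzML has no standard slot for
vendor status logs or tune files; the native dialect carries such data
under `Parameters`, and no mzML mapping is invented for it. Collection
scanning sorts entries lexicographically, so every downstream ordering is
independent of OS directory iteration; per-file reads are independent and
`--jobs N` must (and tests verify it does) produce output identical to
sequential execution. Files that fail to read are collected into a
`Failed` section of the grouped JSON instead of aborting the run.

## Reporting

Flattening joins tree keys with `/` (literal separators
backslash-escaped, so the mapping is lossless) in sorted depth-first
order. A term-matching table — bundled TSV registry plus optional user
TSVs, user rows overriding bundled ones on the (origin, instrument,
label) key — selects and orders what a guideline wants. Matching tries
the exact path first, then a suffix pattern so one row covers
instrument-class layout variants; a pattern matching several *different*
values is an error, never a guess. Required terms with no match render as
`(not recorded)` — publication tables must show gaps. The bundled `miape`
registry is re-derived from the MIAPE-MS guideline and the `jpr` registry
from typical journal checklists; no byte-compatibility with any other
tool's term tables is claimed. Export writes one deterministic two-column
TSV per group (tabs in values become spaces, with a warning) and/or an
XLSX workbook with one sheet per group plus a `files` sheet; styling stops
at a bold header row. Group ids (1…G by first occurrence in lexicographic
file order) are the stable, human-citable names of the groups.

## The synthetic generator

The generator emulates the structure the tool exists for: `n_files`
records drawn (seeded, weighted) from a small number of instrument-method
templates, with per-file fields randomized — timestamps advancing ~37 min
per injection across the series, sample ids, vials, comments — and
optional drift events. Defaults model a routine core-facility batch: the
bundled `qexactive_nlc_<k>` templates (k = 0…5) pair an orbitrap-style MS
tree (tune, MS1/MS2 method blocks) with an EASY-nLC-style LC module whose
3-step gradient lives in method text; the `qexactive_ms_<k>` family is
MS-only with the flat layout mzML can express and is used for
cross-format emission. All parameter values are invented; no statistical
fidelity to real vendor tune files is attempted — which is the main limit
on what passing tests say about real data: they establish the correctness
of the reduction, parsing and reporting machinery, not coverage of every
vendor quirk in the wild.

Drift is a step change: an event `(file_index, tree_path, new_value)`
applies from its index onward, because a persistent unnoticed change is
the scenario that matters over a long series; a point glitch is two paired
events, the second restoring the original. Ground truth is computed from
the template identity plus the *effective* value of every drifted path
(so a restored value correctly re-merges groups), never via the hashing
or grouping code it validates. The same seed yields a byte-identical
corpus.

## Problem sizes and numerical choices

The test suite exercises partitions up to 500 files over up to 6
templates, checks hash/deep-equality agreement over 10⁴ random tree pairs,
and verifies the O(N²) all-pairs oracle partition at every size; the
acceptance script uses a 200-file, 4-template corpus with two drift
events. These sizes mirror the "hundreds of files" regime the tool
targets while keeping a full run in seconds. There are no numeric
tolerances anywhere: every comparison is exact by construction (text-level
decimals, canonical bytes, SHA-256), ties cannot arise, and the degenerate
inputs — empty instrument lists, empty trees, all-failed collections —
have defined behavior (empty tree groups with empty tree; grouping an
empty or fully failed collection is an explicit error, not an empty
success).

## Known limitations

- Proprietary RAW binaries and vendor APIs are out of scope; ingestion is
  the open JSON dialect and mzML headers only (no mzXML or other vendor
  XML).
- The LC dialect is this package's own; real EASY-nLC method strings will
  need a dialect plug-in.
- Strict equality means cosmetic vendor reformatting (e.g. a firmware
  update printing `35.0` as `35.00`) splits groups; that is visible in
  `diff` output but may overstate method diversity.
- The bundled term registries cover the two bundled instrument
  vocabularies; other instruments need user TSV rows.
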
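# mzmeta

Consolidate mass-spectrometry acquisition metadata from hundreds of run
files into the **minimal set of shared parameter groups**, and render each
group as a publication-ready reporting table (MIAPE-style, journal-style,
or your own).

## The problem

LC-MS experiments routinely span hundreds of acquisition files collected
over weeks. Reporting guidelines (MIAPE-MS, journal submission
requirements, repository deposition rules) ask for the instrument settings
behind the data, but extracting them file by file is tedious — so in
practice the settings of a *single* file are often reported for a whole
data set. That hides **parameter drift**: an instrument setting changing
mid-series, with consequences for quality control and reproducibility.

`mzmeta` is written for core facilities and proteomics/metabolomics labs.
It reads per-file metadata (an open JSON dialect, or the header sections of
mzML), strips the fields that legitimately vary per file (file name,
acquisition timestamp, sample information, plus any user-listed tree
paths), and partitions the collection so that files sharing *all* relevant
parameters land in one group.

## The core reduction

Each file's instrument parameters form an ordered tree *T* of string keys
over scalar leaves. Grouping is by content hash

    h(T) = SHA-256( canonical(T) )

where `canonical(T)` serializes the tree with keys sorted at every level
(Unicode NFC, code-point order) and a fixed scalar rendering — decimals by
their exact source text, so `35.0` and `35.00` stay distinct and hashing is
reproducible across platforms. Files with equal hashes form one group; the
partition is provably minimal (any two groups differ in at least one leaf,
which `mzmeta diff` reports), deterministic, and independent of input order
and concurrency. LC gradient programs embedded as method text are parsed
into the tree first, so a changed %B step separates groups like any other
setting.

## Worked example

Simulate a 12-file collection drawn from two method templates, with one
collision-energy drift event injected at file 8, then group and inspect:

```text
$ mzmeta simulate --spec sim.json --out corpus
12 file(s) in 4 ground-truth group(s) -> corpus

$ mzmeta group --input corpus --out grouped.json
4 group(s), 12 file(s), 0 failed -> grouped.json

$ mzmeta diff --input grouped.json | cut -f1-4 | head -5
group_a group_b path                                                            value_a
1       2       Q Exactive - Orbitrap_MS/Ion source/Spray voltage [kV]          2.10
1       2       Q Exactive - Orbitrap_MS/Method/MS2/Normalized collision energy 27.0
1       2       Q Exactive - Orbitrap_MS/Method/MS2/Top N                       10
1       2       Thermo EASY-nLC/Gradient/01/%B                                  38.0
```

Two templates × the drift event give 4 groups (each template splits at file
8 where the normalized collision energy changed to 33.0); the pairwise diff
names exactly the parameter paths separating groups. Rendering the
guideline tables:

```text
$ mzmeta report --input grouped.json --out report --origin miape \
      --instruments "Thermo EASY-nLC" --instruments "Q Exactive - Orbitrap_MS"
$ head -7 report/group_1.txt
Instrument model        Q Exactive - Orbitrap_MS
Spray voltage (kV)      2.10
Capillary temperature (°C)      275
Polarity        positive
MS1 resolution  70000
MS1 AGC target  3000000
MS1 scan range (m/z)    300-1750
```

One two-column TSV per group (plus a `groups.xlsx` workbook with
`--formats tsv,xlsx`), rows in the guideline's display order; required
terms the data does not carry appear as `(not recorded)` rather than being
dropped. The bundled `miape` and `jpr` term registries are re-derived from
the public guideline texts and can be overridden with `--terms your.tsv`.

## Library use

Everything the CLI does is a function call away:

```python
from mzmeta import GeneratorSpec, generate_metadata, group_files, diff_groups
from mzmeta.synthetic import default_templates

spec = GeneratorSpec(n_files=200, templates=default_templates(3), seed=42)
records, truth = generate_metadata(spec)
gc = group_files(records)
assert [g.file_names for g in gc.groups] == truth
```

Interchange formats (per-file metadata dialect, grouped JSON) are
documented as JSON-Schema files in `src/mzmeta/data/`.

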
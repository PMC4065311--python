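"""Readers and writers for the external formats of the immunosignaturing pipeline.

Formats handled here:

* **GPR** (GenePix Results, minimal single-channel dialect): a header block of
  ``key=value`` lines followed by a tab-separated table with ``ID``, 1-based
  ``Block``/``Row``/``Column`` coordinates and one intensity column
  (default ``F635 Median``).
* **GAL-style peptide library tables** mapped to :class:`PeptideLibrary`.
* **FASTA** proteomes (via Biopython) for target mapping.
* **TSV** signature tables (sequence, per-study binding ratios,
  cross-membership flags) and sample-metadata tables.

Peptide identity is keyed by ``peptide_id`` throughout, never by sequence:
random libraries can in principle contain duplicate sequences.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .signature_selection import PeptideSet

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_RESIDUES = "BUXZ"
DEFAULT_LINKER = "GSC"
DEFAULT_INTENSITY_COLUMN = "F635 Median"

STRAINS = ("MRL/lpr", "MRL/mp", "C3H/HeJ")
PHENOTYPES = ("high_floater", "low_floater")

SCALE_RAW = "raw"
SCALE_MEDIAN_NORMALIZED = "median_normalized"
SCALE_LOG10 = "log10"
SCALES = (SCALE_RAW, SCALE_MEDIAN_NORMALIZED, SCALE_LOG10)


class FormatError(ValueError):
    """Raised when an external file violates the expected dialect."""


# ---------------------------------------------------------------------------
# Peptide library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideLibrary:
    """Ordered collection of array peptides.

    ``entries`` is indexed by ``peptide_id`` and carries ``sequence`` plus
    1-based ``block``/``row``/``column`` GenePix coordinates. Every sequence
    is expected to terminate in the invariant C-terminal linker (``GSC`` by
    default) — an attachment-chemistry artifact, not epitope content.
    """

    entries: pd.DataFrame
    linker: str = DEFAULT_LINKER

    def __post_init__(self) -> None:
        required = {"sequence", "block", "row", "column"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"library table missing columns: {sorted(missing)}")
        if self.entries.index.has_duplicates:
            dupes = self.entries.index[self.entries.index.duplicated()].tolist()
            raise ValueError(f"duplicate peptide ids: {dupes[:5]}")
        seqs = self.entries["sequence"]
        if (seqs.str.len() == 0).any():
            raise ValueError("empty peptide sequence in library")
        bad = seqs[~seqs.str.fullmatch(f"[{AMINO_ACIDS}]+")]
        if len(bad):
            raise ValueError(
                f"non amino-acid characters in sequences: {bad.index[:5].tolist()}"
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, int, int, int]],
        linker: str = DEFAULT_LINKER,
    ) -> "PeptideLibrary":
        df = pd.DataFrame.from_records(
            list(records),
            columns=["peptide_id", "sequence", "block", "row", "column"],
        ).set_index("peptide_id")
        return cls(df, linker=linker)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> pd.Index:
        return self.entries.index

    @property
    def sequences(self) -> pd.Series:
        return self.entries["sequence"]

    def enforce_linker(self) -> None:
        """Raise unless every sequence ends with the configured linker."""
        bad = self.sequences[~self.sequences.str.endswith(self.linker)]
        if len(bad):
            raise ValueError(
                f"{len(bad)} sequences do not end with linker {self.linker!r}: "
                f"{bad.index[:5].tolist()}"
            )

    def variable_regions(self) -> pd.Series:
        """Sequences with the C-terminal linker removed."""
        n = len(self.linker)
        return self.sequences.str.slice(0, -n) if n else self.sequences


def write_library(path: str | Path, library: PeptideLibrary) -> None:
    """Write a GAL-style tab-separated library table."""
    df = library.entries.reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_library(path: str | Path, linker: str = DEFAULT_LINKER) -> PeptideLibrary:
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "sequence": str})
    if "peptide_id" not in df.columns:
        raise FormatError(f"{path}: library table needs a peptide_id column")
    return PeptideLibrary(df.set_index("peptide_id"), linker=linker)


# ---------------------------------------------------------------------------
# Samples and intensity matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRecord:
    """One hybridized slide: a (mouse, technical replicate) pair.

    ``phenotype`` is the forced-swim-test grouping (high vs low floater) and
    is only meaningful for MRL/lpr mice. For presymptomatic samples it holds
    the *future* phenotype observed at a later age, which is what the
    behavior-prediction contrasts require.
    """

    sample_id: str
    mouse_id: str
    strain: str
    age_months: float
    replicate: int = 1
    phenotype: str | None = None
    study: int = 1

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}")
        if self.phenotype is not None:
            if self.phenotype not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {self.phenotype!r}")
            if self.strain != "MRL/lpr":
                raise ValueError("phenotype is only defined for MRL/lpr samples")
        if self.replicate < 1:
            raise ValueError("replicate numbering is 1-based")


SAMPLE_COLUMNS = ["mouse_id", "strain", "age_months", "replicate", "phenotype", "study"]


def samples_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Metadata table indexed by sample_id; one row per slide."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows).set_index("sample_id")[SAMPLE_COLUMNS]
    key = df.reset_index()[["study", "mouse_id", "replicate"]]
    if key.duplicated().any():
        raise ValueError("(mouse_id, replicate) must be unique within a study")
    return df


@dataclass
class IntensityMatrix:
    """Peptides x samples intensity grid with metadata and a scale tag.

    ``values`` is indexed by peptide_id (library order) with one column per
    sample; ``samples`` is the metadata table indexed by sample_id.
    ``scale`` advances only raw -> median_normalized -> log10.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = SCALE_RAW

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns and sample metadata rows disagree")
        if self.scale != SCALE_LOG10 and (self.values.to_numpy() <= 0).any():
            raise ValueError(
                f"{self.scale} intensities must be strictly positive "
                "(log transforms downstream)"
            )

    @property
    def n_peptides(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, mask: pd.Series) -> "IntensityMatrix":
        ids = self.samples.index[mask.to_numpy(dtype=bool)]
        return IntensityMatrix(self.values[ids], self.samples.loc[ids], self.scale)


def concat_matrices(matrices: Sequence[IntensityMatrix]) -> IntensityMatrix:
    """Column-wise concatenation (e.g. the two studies of a cohort)."""
    scales = {m.scale for m in matrices}
    if len(scales) != 1:
        raise ValueError(f"cannot concatenate mixed scales {sorted(scales)}")
    first = matrices[0].values.index
    for m in matrices[1:]:
        if not m.values.index.equals(first):
            raise ValueError("matrices are not on the same peptide library")
    return IntensityMatrix(
        pd.concat([m.values for m in matrices], axis=1),
        pd.concat([m.samples for m in matrices], axis=0),
        scale=scales.pop(),
    )


# ---------------------------------------------------------------------------
# GPR files
# ---------------------------------------------------------------------------

_GPR_META_KEYS = ("sample_id", "mouse_id", "strain", "age_months", "replicate",
                  "phenotype", "study")


def write_gpr(
    path: str | Path,
    library: PeptideLibrary,
    intensities: Sequence[float] | np.ndarray | pd.Series,
    sample: SampleRecord,
    intensity_column: str = DEFAULT_INTENSITY_COLUMN,
) -> None:
    """Write one slide as a minimal single-channel GPR file.

    Sample metadata is embedded as header ``key=value`` lines so a cohort of
    GPR files is self-describing even without the sidecar metadata table.
    """
    vals = pd.Series(np.asarray(intensities, dtype=float), index=library.ids)
    meta = dataclasses.asdict(sample)
    lines = ["Type=GenePix Results (immunosig minimal dialect)"]
    for key in _GPR_META_KEYS:
        value = meta[key]
        lines.append(f"{key}={'' if value is None else value}")
    lines.append("\t".join(["ID", "Block", "Row", "Column", intensity_column]))
    coords = library.entries
    for pid, inten in vals.items():
        row = coords.loc[pid]
        lines.append(
            f"{pid}\t{row['block']}\t{row['row']}\t{row['column']}\t{inten!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_gpr_sample(header: dict[str, str], path: str | Path) -> SampleRecord:
    try:
        return SampleRecord(
            sample_id=header["sample_id"],
            mouse_id=header["mouse_id"],
            strain=header["strain"],
            age_months=float(header["age_months"]),
            replicate=int(header["replicate"]),
            phenotype=header.get("phenotype") or None,
            study=int(header.get("study", 1)),
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise FormatError(f"{path}: GPR header lacks sample key {exc}") from exc


def read_gpr(
    path: str | Path,
    library: PeptideLibrary,
    sample: SampleRecord | None = None,
    intensity_column: str = DEFAULT_INTENSITY_COLUMN,
) -> IntensityMatrix:
    """Read one GPR file into a single-sample raw-scale matrix.

    Rows are re-ordered to library order; every library peptide must appear
    exactly once. ``sample`` overrides the metadata embedded in the header.
    """
    path = Path(path)
    header: dict[str, str] = {}
    table_start = None
    lines = path.read_text().splitlines()
    for i, line in enumerate(lines):
        if "=" in line and "\t" not in line:
            key, _, value = line.partition("=")
            header[key.strip()] = value.strip()
        elif line.strip():
            table_start = i
            break
    if table_start is None:
        raise FormatError(f"{path}: no data table found")
    columns = lines[table_start].split("\t")
    if "ID" not in columns or intensity_column not in columns:
        raise FormatError(
            f"{path}: table needs 'ID' and {intensity_column!r} columns, got {columns}"
        )
    id_pos = columns.index("ID")
    val_pos = columns.index(intensity_column)

    seen: dict[str, float] = {}
    for lineno, line in enumerate(lines[table_start + 1:], start=table_start + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        pid = fields[id_pos]
        try:
            value = float(fields[val_pos])
        except (ValueError, IndexError):
            raise FormatError(f"{path}:{lineno}: non-numeric intensity") from None
        if pid in seen:
            raise FormatError(f"{path}: duplicate peptide id {pid!r}")
        seen[pid] = value

    missing = library.ids.difference(seen.keys())
    if len(missing):
        raise FormatError(f"{path}: missing peptide id {missing[0]!r} "
                          f"({len(missing)} missing in total)")
    extra = set(seen) - set(library.ids)
    if extra:
        raise FormatError(f"{path}: {len(extra)} ids not in library, "
                          f"e.g. {sorted(extra)[:3]}")

    if sample is None:
        sample = _parse_gpr_sample(header, path)
    values = pd.DataFrame(
        {sample.sample_id: [seen[pid] for pid in library.ids]}, index=library.ids
    )
    return IntensityMatrix(values, samples_frame([sample]), scale=SCALE_RAW)


def write_cohort_gpr(
    directory: str | Path,
    matrix: IntensityMatrix,
    library: PeptideLibrary,
    intensity_column: str = DEFAULT_INTENSITY_COLUMN,
) -> Path:
    """Write one GPR per sample plus a ``samples.tsv`` sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if matrix.scale != SCALE_RAW:
        raise ValueError("cohorts are exchanged as raw intensities")
    files = []
    for sid, meta in matrix.samples.iterrows():
        rec = SampleRecord(
            sample_id=sid,
            mouse_id=meta["mouse_id"],
            strain=meta["strain"],
            age_months=float(meta["age_months"]),
            replicate=int(meta["replicate"]),
            phenotype=None if pd.isna(meta["phenotype"]) else meta["phenotype"],
            study=int(meta["study"]),
        )
        fname = f"{sid}.gpr"
        write_gpr(directory / fname, library, matrix.values[sid], rec,
                  intensity_column=intensity_column)
        files.append(fname)
    sidecar = directory / "samples.tsv"
    meta = matrix.samples.copy()
    meta["gpr_file"] = files
    meta.reset_index().to_csv(sidecar, sep="\t", index=False)
    return sidecar


def read_cohort_gpr(
    directory: str | Path,
    library: PeptideLibrary,
    intensity_column: str = DEFAULT_INTENSITY_COLUMN,
) -> IntensityMatrix:
    """Assemble the cohort written by :func:`write_cohort_gpr`."""
    directory = Path(directory)
    meta = pd.read_csv(directory / "samples.tsv", sep="\t")
    parts = []
    for _, row in meta.iterrows():
        rec = SampleRecord(
            sample_id=row["sample_id"],
            mouse_id=str(row["mouse_id"]),
            strain=row["strain"],
            age_months=float(row["age_months"]),
            replicate=int(row["replicate"]),
            phenotype=None if pd.isna(row["phenotype"]) else row["phenotype"],
            study=int(row["study"]),
        )
        parts.append(read_gpr(directory / row["gpr_file"], library, sample=rec,
                              intensity_column=intensity_column))
    return concat_matrices(parts)


# ---------------------------------------------------------------------------
# Proteome FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    description: str
    sequence: str

    @property
    def has_ambiguous(self) -> bool:
        return any(c in AMBIGUOUS_RESIDUES for c in self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def read_proteome(path: str | Path) -> list[ProteinRecord]:
    """Read an amino-acid FASTA file; sequences are uppercased, U/B/Z/X retained."""
    records = []
    ids = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise FormatError(f"{path}: duplicate protein id {rec.id!r}")
        ids.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(rec.id, desc, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_proteome(path: str | Path, proteins: Sequence[ProteinRecord]) -> None:
    recs = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description=p.description)
        for p in proteins
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Signature tables (the layout of the printed peptide-set tables)
# ---------------------------------------------------------------------------

_FLAG_MARK = "x"


def write_signature_table(pset: "PeptideSet", path: str | Path,
                          header_comment: str | None = None) -> None:
    """Write a peptide set as TSV: sequence, per-study ratios, membership flags.

    Rows are sorted lexicographically by sequence (the ordering of the
    published tables); boolean flag columns are serialized as ``x``/empty.
    """
    if len(pset.members) == 0:
        raise ValueError(f"refusing to write empty signature {pset.name!r}")
    df = pset.members.copy()
    df.index.name = "peptide_id"
    df = df.reset_index()
    front = ["peptide_id"] + [c for c in ("sequence",) if c in df.columns]
    ratio_cols = [c for c in df.columns if c.startswith("ratio")]
    flag_cols = [c for c in df.columns if df[c].dtype == bool]
    df = df[front + ratio_cols + flag_cols]
    for c in flag_cols:
        df[c] = df[c].map({True: _FLAG_MARK, False: ""})
    sort_key = "sequence" if "sequence" in df.columns else "peptide_id"
    df = df.sort_values(sort_key, kind="stable")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"# signature={pset.name}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_signature_table(path: str | Path, name: str | None = None) -> "PeptideSet":
    from .signature_selection import PeptideSet

    sig_name = name
    with open(path) as fh:
        for line in fh:
            if line.startswith("# signature="):
                sig_name = sig_name or line.partition("=")[2].strip()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"peptide_id": str})
    if "peptide_id" not in df.columns:
        if "sequence" not in df.columns:
            raise FormatError(f"{path}: need a peptide_id or sequence column")
        df["peptide_id"] = df["sequence"]
    df = df.set_index("peptide_id")
    for c in df.columns:
        if c.startswith("in_"):
            df[c] = df[c].fillna("").astype(str).str.strip().isin([_FLAG_MARK, "True"])
    return PeptideSet(name=sig_name or Path(path).stem, members=df, provenance={})
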
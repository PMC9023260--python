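"""Readers and writers for the formats the motif pipeline touches.

The pipeline consumes 3'UTR sequences (FASTA, one record per transcript with
``gene_id|transcript_id`` headers), a differential-expression summary table
(TSV produced by standard DE tools such as DESeq2 -- consumed, never
computed), and a packaged panel of EMSA probe oligomers with their reported
gel-shift outcomes.

All sequences are normalised to the RNA alphabet {A, C, G, U} (T -> U,
uppercased) at ingest so that DNA-context motifs such as GAAA and RNA-context
motifs such as UAUUUAU live in one alphabet.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

#: DE categorisation defaults: a gene needs >= 10 mean reads to count as
#: detected, and adjusted p < 0.05 with |log2FC| > 1 to be differentially
#: expressed.
DETECTION_THRESHOLD = 10.0
P_THRESHOLD = 0.05
FC_THRESHOLD = 1.0

CATEGORIES = ("up", "down", "unchanged", "excluded")


class PipelineError(Exception):
    """Base class for errors raised by this package."""


class FastaParseError(PipelineError):
    """Malformed FASTA input."""


class SequenceAlphabetError(PipelineError):
    """A sequence contains characters outside the accepted alphabet."""


class SchemaError(PipelineError):
    """A tabular input is missing required columns."""


class TableParseError(PipelineError):
    """A tabular input has an unparseable value."""


def normalize_sequence(raw: str, *, where: str = "sequence") -> str:
    """Uppercase, convert T -> U, and validate against {A, C, G, U}.

    ``where`` names the offending record in the error message.
    """
    seq = raw.upper().replace("T", "U")
    for pos, ch in enumerate(seq):
        if ch not in RNA_ALPHABET:
            raise SequenceAlphabetError(
                f"illegal character {ch!r} at position {pos} in {where}"
            )
    return seq


@dataclass(frozen=True)
class UTRRecord:
    """One gene/transcript 3'UTR sequence.

    ``sequence`` is RNA over {A, C, G, U}; ``length`` always equals
    ``len(sequence)``.
    """

    gene_id: str
    transcript_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_raw(cls, gene_id: str, transcript_id: str, raw_sequence: str) -> "UTRRecord":
        seq = normalize_sequence(
            raw_sequence, where=f"record {gene_id}|{transcript_id}"
        )
        return cls(gene_id, transcript_id, seq)


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression summary plus its assigned category.

    ``log2fc`` and ``padj`` may be ``None`` (DE tools emit NA for filtered
    genes); such genes are categorised ``unchanged``, not dropped, because
    they are detected but not differentially expressed.
    """

    gene_id: str
    read_support: float
    log2fc: float | None
    padj: float | None
    category: str


@dataclass(frozen=True)
class ProbeRecord:
    """A named RNA oligomer from the EMSA probe panel.

    ``are_class`` is ``7mer`` iff the sequence contains UAUUUAU, ``5mer_only``
    iff it contains AUUUA but no UAUUUAU, else ``none``. ``reported_binding``
    is the gel-shift outcome; ``provenance`` records whether that outcome is
    stated in the source text or inferred from the single-7-mer binding rule.
    """

    name: str
    sequence: str
    are_class: str
    reported_binding: str
    provenance: str


def _parse_header(header: str) -> tuple[str, str]:
    """Split a ``gene|transcript`` FASTA id; a single token serves as both."""
    token = header.split()[0] if header.split() else header
    if "|" in token:
        gene_id, transcript_id = token.split("|", 1)
    else:
        gene_id = transcript_id = token
    return gene_id, transcript_id


def read_utr_fasta(path: str | Path) -> list[UTRRecord]:
    """Read 3'UTR records from FASTA, normalising sequences to RNA.

    Headers are ``gene_id|transcript_id`` (pipe-delimited; a lone token is
    used as both ids). Record order is preserved; duplicate genes are kept --
    isoform selection happens downstream in :func:`select_longest_utr`.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"FASTA file not found: {path}")
    with open(path) as handle:
        # Biopython silently skips leading junk; fail loudly instead.
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected '>' header, got {line.strip()[:40]!r}"
                )
            break
        handle.seek(0)
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            gene_id, transcript_id = _parse_header(rec.id)
            records.append(UTRRecord.from_raw(gene_id, transcript_id, str(rec.seq)))
    return records


def write_utr_fasta(records: Iterable[UTRRecord], path: str | Path) -> None:
    """Write UTR records as FASTA with ``gene|transcript`` headers."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=f"{r.gene_id}|{r.transcript_id}", description="")
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def select_longest_utr(records: Iterable[UTRRecord]) -> dict[str, UTRRecord]:
    """Keep one 3'UTR per gene: the longest isoform.

    Equal-length isoforms are resolved by lexicographically smallest
    transcript id, a deterministic convention.
    """
    best: dict[str, UTRRecord] = {}
    for rec in records:
        cur = best.get(rec.gene_id)
        if cur is None:
            best[rec.gene_id] = rec
        elif (-rec.length, rec.transcript_id) < (-cur.length, cur.transcript_id):
            best[rec.gene_id] = rec
    return best


def categorize(
    read_support: float,
    log2fc: float | None,
    padj: float | None,
    *,
    detection_threshold: float = DETECTION_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
) -> str:
    """Assign the DE category for one gene.

    ``excluded`` below the detection threshold; ``up``/``down`` for
    significant fold changes beyond the threshold; otherwise ``unchanged``
    (including genes with missing log2FC or adjusted p).
    """
    if read_support < detection_threshold:
        return "excluded"
    if log2fc is None or padj is None:
        return "unchanged"
    if padj < p_threshold:
        if log2fc > fc_threshold:
            return "up"
        if log2fc < -fc_threshold:
            return "down"
    return "unchanged"


_DE_COLUMNS = ("gene_id", "read_support", "log2fc", "padj")


def read_de_table(
    path: str | Path,
    detection_threshold: float = DETECTION_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
) -> list[DERecord]:
    """Read a DE results TSV and categorise every gene.

    Expects header columns ``gene_id, read_support, log2fc, padj``; missing
    values may be encoded as ``NA`` or left empty. Comment lines starting
    with ``#`` are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"DE table not found: {path}")
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - malformed TSV
        raise TableParseError(f"{path}: {exc}") from exc
    missing = [c for c in _DE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    def _num(value: str, column: str, row: int) -> float | None:
        if value in ("", "NA", "NaN", "nan"):
            return None
        try:
            return float(value)
        except ValueError:
            raise TableParseError(
                f"{path}: row {row}: non-numeric {column} value {value!r}"
            ) from None

    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        read_support = _num(row.read_support, "read_support", idx)
        if read_support is None:
            raise TableParseError(f"{path}: row {idx}: read_support is missing")
        log2fc = _num(row.log2fc, "log2fc", idx)
        padj = _num(row.padj, "padj", idx)
        category = categorize(
            read_support,
            log2fc,
            padj,
            detection_threshold=detection_threshold,
            p_threshold=p_threshold,
            fc_threshold=fc_threshold,
        )
        records.append(DERecord(row.gene_id, read_support, log2fc, padj, category))
    return records


def write_de_table(records: Iterable[DERecord], path: str | Path) -> None:
    """Write DE records in the TSV dialect :func:`read_de_table` accepts."""

    def _fmt(v: float | None) -> str:
        return "NA" if v is None else repr(v)

    with open(path, "w") as handle:
        handle.write("gene_id\tread_support\tlog2fc\tpadj\n")
        for r in records:
            handle.write(
                f"{r.gene_id}\t{r.read_support!r}\t{_fmt(r.log2fc)}\t{_fmt(r.padj)}\n"
            )


def load_probe_panel() -> list[ProbeRecord]:
    """Load the packaged 17-probe EMSA panel.

    The three Elavl2 7-mer probes, Gm-csf, and Tnf-alpha have binding stated
    in the source text; Fgf23 and the single-5-mer probes have non-binding
    stated; the remaining 7-mer probes carry an inferred ``bind`` outcome
    (single-ARE-7-mer probes shifted in the gel assays).
    """
    data = importlib.resources.files("aremotif.data").joinpath("probe_panel.tsv")
    records = []
    lines = data.read_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    for line in lines[1:]:
        fields = dict(zip(header, line.split("\t")))
        records.append(
            ProbeRecord(
                name=fields["name"],
                sequence=normalize_sequence(fields["sequence"], where=fields["name"]),
                are_class=fields["are_class"],
                reported_binding=fields["reported_binding"],
                provenance=fields["provenance"],
            )
        )
    return records


def write_probe_panel(records: Iterable[ProbeRecord], path: str | Path) -> None:
    """Export a probe panel in the packaged TSV dialect."""
    with open(path, "w") as handle:
        handle.write("name\tsequence\tare_class\treported_binding\tprovenance\n")
        for r in records:
            handle.write(
                f"{r.name}\t{r.sequence}\t{r.are_class}\t{r.reported_binding}\t{r.provenance}\n"
            )
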
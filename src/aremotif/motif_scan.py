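"""Locate, count, delete, and contextualise ARE and GAAA motifs.

The motifs of interest are exact k-mers: the ARE pentamer AUUUA (the minimal
ARE core), the 7-mer UAUUUAU (the minimal element required for ZFP36L2
binding in gel-shift assays), and GAAA (the element preferred by the
stabilising RBP ELAVL2). Occurrences are counted overlapping by default --
class II AREs are blocks of overlapping pentamers and a non-overlapping scan
would undercount them -- with a non-overlapping mode exposed for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .io_tables import PipelineError, UTRRecord

PENTAMER = "AUUUA"
SEVENMER = "UAUUUAU"
GAAA = "GAAA"


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: half-open interval [start, end) on the sequence."""

    motif: str
    start: int
    end: int


@dataclass(frozen=True)
class MotifCensus:
    """Per-gene motif counts over one (longest-isoform) 3'UTR."""

    gene_id: str
    utr_length: int
    n_5mer: int
    n_7mer: int
    n_GAAA: int


def find_motif(
    sequence: str, motif: str, *, overlapping: bool = True
) -> list[MotifHit]:
    """All occurrences of ``motif`` in ``sequence``, sorted by start.

    Overlapping occurrences are included by default; with
    ``overlapping=False`` the scan restarts after each hit.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    hits = []
    step = 1 if overlapping else len(motif)
    i = sequence.find(motif)
    while i != -1:
        hits.append(MotifHit(motif, i, i + len(motif)))
        i = sequence.find(motif, i + step)
    return hits


def count_motif(sequence: str, motif: str, *, overlapping: bool = True) -> int:
    """Number of (by default overlapping) occurrences of ``motif``."""
    return len(find_motif(sequence, motif, overlapping=overlapping))


def census(utr: UTRRecord, *, overlapping: bool = True) -> MotifCensus:
    """Count AUUUA, UAUUUAU, and GAAA occurrences in one 3'UTR."""
    return MotifCensus(
        gene_id=utr.gene_id,
        utr_length=utr.length,
        n_5mer=count_motif(utr.sequence, PENTAMER, overlapping=overlapping),
        n_7mer=count_motif(utr.sequence, SEVENMER, overlapping=overlapping),
        n_GAAA=count_motif(utr.sequence, GAAA, overlapping=overlapping),
    )


def classify_probe(sequence: str) -> str:
    """Predict ZFP36L2 binding from the 7-mer rule.

    Gel-shift assays show binding requires at least one UAUUUAU; a lone
    AUUUA pentamer is insufficient. Returns ``"bind"`` or ``"no_bind"``.
    """
    return "bind" if count_motif(sequence, SEVENMER) >= 1 else "no_bind"


def delete_motif(sequence: str, motif: str) -> str:
    """Remove every occurrence of ``motif``, leftmost first, to exhaustion.

    Deleting an occurrence can join flanks into a fresh occurrence, so the
    scan repeats until none remains: the result is guaranteed motif-free and
    its length differs from the input by a multiple of ``len(motif)``.
    This reproduces construct arithmetic such as deleting three planted
    7-mers from a 2529-nt 3'UTR to obtain a 2508-nt variant (21 nt = 3 x 7).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    while True:
        i = sequence.find(motif)
        if i == -1:
            return sequence
        sequence = sequence[:i] + sequence[i + len(motif):]


def extract_windows(
    sequence: str, motif: str, flank: int = 12, *, overlapping: bool = True
) -> list[str]:
    """Sequence windows of ``flank`` nt either side of each motif hit.

    The default flank of 12 nt gives 31-nt windows around the 7-mer, the
    roughly 30-nt context used as input for de novo motif discovery.
    Windows at the sequence edges are clipped.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return [
        sequence[max(0, h.start - flank): min(len(sequence), h.end + flank)]
        for h in find_motif(sequence, motif, overlapping=overlapping)
    ]


def intermotif_distances(
    sequence: str, motif: str, *, overlapping: bool = True
) -> list[int]:
    """Gaps between consecutive motif hits: next start minus previous end.

    A downstream motif 11 nt after the seed gives distance 11; overlapping
    hits give negative distances.
    """
    hits = find_motif(sequence, motif, overlapping=overlapping)
    return [b.start - a.end for a, b in zip(hits, hits[1:])]


def write_census_tsv(
    censuses: Iterable[MotifCensus],
    path: str | Path,
    *,
    header_lines: Iterable[str] = (),
) -> None:
    """Write censuses as TSV (gene_id, utr_length, n_5mer, n_7mer, n_GAAA)."""
    with open(path, "w") as handle:
        for line in header_lines:
            handle.write(f"# {line}\n")
        handle.write("gene_id\tutr_length\tn_5mer\tn_7mer\tn_GAAA\n")
        for c in censuses:
            handle.write(
                f"{c.gene_id}\t{c.utr_length}\t{c.n_5mer}\t{c.n_7mer}\t{c.n_GAAA}\n"
            )


def read_census_tsv(path: str | Path) -> dict[str, MotifCensus]:
    """Read a census TSV back into a gene -> census mapping."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "utr_length", "n_5mer", "n_7mer", "n_GAAA"}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(
            f"{path}: missing census column(s): {', '.join(sorted(missing))}"
        )
    return {
        row.gene_id: MotifCensus(
            gene_id=str(row.gene_id),
            utr_length=int(row.utr_length),
            n_5mer=int(row.n_5mer),
            n_7mer=int(row.n_7mer),
            n_GAAA=int(row.n_GAAA),
        )
        for row in df.itertuples(index=False)
    }


def write_windows_fasta(
    utrs: Iterable[UTRRecord],
    path: str | Path,
    motif: str = SEVENMER,
    flank: int = 12,
) -> int:
    """Export motif-centred windows as FASTA (headers ``gene_id|hit_index``).

    Returns the number of windows written. Suitable as input for external
    de novo motif tools.
    """
    n = 0
    with open(path, "w") as handle:
        for utr in utrs:
            for idx, window in enumerate(extract_windows(utr.sequence, motif, flank)):
                handle.write(f">{utr.gene_id}|{idx}\n{window}\n")
                n += 1
    return n
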
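"""Synthetic 3'UTR cohorts with category-dependent planted motif densities.

The generator emulates the statistical structure the analysis assumes: a
cohort of detected genes split into up/down/unchanged DE categories (default
sizes 549/603/15684, the spleen study structure), each gene carrying one
3'UTR whose background is i.i.d. with a configurable A/U share and into
which 7-mer ARE, lone-pentamer, and GAAA motifs are planted at
category-dependent Poisson rates. A matching DE table is emitted whose
categorisation under the default thresholds recovers the configured sizes
exactly, plus a truth table of planted counts per gene.

Planted counts are Poisson by default so enrichment is distributional (a
``fixed`` mode plants deterministic counts for exact tests). Everything is
driven by one seeded random stream, so a cohort is byte-identical across
runs given the same configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_tables import DERecord, UTRRecord, categorize, write_de_table, write_utr_fasta
from .motif_scan import GAAA, PENTAMER, SEVENMER


class GenerationError(Exception):
    """Raised when a sequence cannot be generated as requested."""


_LETTERS = np.frombuffer(b"AUGC", dtype=np.uint8)
_CATEGORIES = ("up", "down", "unchanged")


def _default_7mer_rates() -> dict[str, float]:
    return {"up": 1.2, "down": 0.3, "unchanged": 0.3}


def _default_gaaa_rates() -> dict[str, float]:
    return {"up": 4.0, "down": 2.0, "unchanged": 2.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort recipe. Defaults mirror the spleen study cohort structure."""

    n_up: int = 549
    n_down: int = 603
    n_unchanged: int = 15684
    #: log-normal 3'UTR length law: median in nt and log-scale dispersion
    utr_length_median: float = 800.0
    utr_length_sigma: float = 0.8
    background_AU_fraction: float = 0.55
    planted_7mer_rate: Mapping[str, float] = field(default_factory=_default_7mer_rates)
    planted_5mer_extra_rate: float = 0.5
    planted_GAAA_rate: Mapping[str, float] = field(default_factory=_default_gaaa_rates)
    #: mean |log2FC| for DE genes; must exceed the DE threshold of 1
    effect_log2fc: float = 2.5
    planting: str = "poisson"  # or "fixed"
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_up, self.n_down, self.n_unchanged) < 0:
            raise ValueError("category sizes must be >= 0")
        if not 0.0 <= self.background_AU_fraction <= 1.0:
            raise ValueError("background_AU_fraction must be in [0, 1]")
        if self.utr_length_median <= 0 or self.utr_length_sigma < 0:
            raise ValueError("invalid 3'UTR length law")
        rates = [self.planted_5mer_extra_rate]
        rates += [self.planted_7mer_rate[c] for c in _CATEGORIES]
        rates += [self.planted_GAAA_rate[c] for c in _CATEGORIES]
        if min(rates) < 0:
            raise ValueError("planted rates must be >= 0")
        if self.effect_log2fc <= 1.0:
            raise ValueError("effect_log2fc must exceed the |log2FC| threshold of 1")
        if self.planting not in ("poisson", "fixed"):
            raise ValueError("planting must be 'poisson' or 'fixed'")


@dataclass(frozen=True)
class TruthRecord:
    gene_id: str
    category: str
    planted_7mer: int
    planted_5mer_extra: int
    planted_GAAA: int


@dataclass(frozen=True)
class SyntheticCohort:
    utrs: list[UTRRecord]
    de_table: list[DERecord]
    truth: dict[str, TruthRecord]
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the FASTA/TSV dialects the ingest module reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "utr_fasta": outdir / "utrs.fasta",
            "de_table": outdir / "de_table.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_utr_fasta(self.utrs, paths["utr_fasta"])
        write_de_table(self.de_table, paths["de_table"])
        with open(paths["truth"], "w") as handle:
            handle.write(
                "gene_id\tcategory\tplanted_7mer\tplanted_5mer_extra\tplanted_GAAA\n"
            )
            for t in self.truth.values():
                handle.write(
                    f"{t.gene_id}\t{t.category}\t{t.planted_7mer}\t"
                    f"{t.planted_5mer_extra}\t{t.planted_GAAA}\n"
                )
        return paths


def _background_codes(
    total: int, au_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. background as ASCII codes: A/U equiprobable within the A/U
    share, G/C equiprobable within the rest."""
    p = np.array(
        [au_fraction / 2, au_fraction / 2, (1 - au_fraction) / 2, (1 - au_fraction) / 2]
    )
    cum = np.cumsum(p)
    cum[-1] = 1.0
    idx = np.searchsorted(cum, rng.random(total), side="right")
    return _LETTERS[idx]


def _plant_into(
    codes: np.ndarray,
    planted: Sequence[tuple[str, int]],
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> None:
    """Overwrite non-overlapping uniform positions with the planted motifs."""
    length = len(codes)
    total = sum(len(m) * c for m, c in planted)
    if total > length:
        raise GenerationError(
            f"cannot plant {total} nt of motifs into a {length}-nt sequence"
        )
    occupied: list[tuple[int, int]] = []
    for motif, count in planted:
        mcodes = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
        mlen = len(motif)
        for _ in range(count):
            for _ in range(max_tries):
                s = int(rng.integers(0, length - mlen + 1))
                if all(s >= e or s + mlen <= b for b, e in occupied):
                    occupied.append((s, s + mlen))
                    codes[s: s + mlen] = mcodes
                    break
            else:
                raise GenerationError(
                    f"failed to place motif {motif!r} after {max_tries} tries"
                )


def generate_utr(
    length: int,
    AU_fraction: float,
    planted: Sequence[tuple[str, int]],
    rng: np.random.Generator,
) -> str:
    """One random RNA sequence with the given planted motifs.

    Background is i.i.d. with the given A/U share; each planted motif is
    written at a uniform position without overlapping another planted motif,
    so the result contains at least the planted number of occurrences of
    each motif (the background may create extras by chance).
    """
    if length < 0:
        raise GenerationError("length must be >= 0")
    codes = _background_codes(length, AU_fraction, rng)
    _plant_into(codes, planted, rng)
    return codes.tobytes().decode("ascii")


def _planted_counts(
    rate: float, n: int, mode: str, rng: np.random.Generator
) -> np.ndarray:
    if mode == "fixed":
        return np.full(n, round(rate), dtype=np.int64)
    return rng.poisson(rate, n)


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate a full cohort: 3'UTRs, DE table, and planted-motif truth.

    Fully reproducible from ``config.seed``: one global stream drives every
    draw in a fixed order.
    """
    if config is None:
        config = SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    sizes = {
        "up": config.n_up,
        "down": config.n_down,
        "unchanged": config.n_unchanged,
    }
    mu = math.log(config.utr_length_median)

    lengths: dict[str, np.ndarray] = {}
    n7: dict[str, np.ndarray] = {}
    n5x: dict[str, np.ndarray] = {}
    ngaaa: dict[str, np.ndarray] = {}
    for cat in _CATEGORIES:
        n = sizes[cat]
        lengths[cat] = np.rint(
            rng.lognormal(mu, config.utr_length_sigma, n)
        ).astype(np.int64)
        n7[cat] = _planted_counts(config.planted_7mer_rate[cat], n, config.planting, rng)
        n5x[cat] = _planted_counts(config.planted_5mer_extra_rate, n, config.planting, rng)
        ngaaa[cat] = _planted_counts(
            config.planted_GAAA_rate[cat], n, config.planting, rng
        )
        # leave head-room so non-overlapping planting always packs
        need = 7 * n7[cat] + 5 * n5x[cat] + 4 * ngaaa[cat]
        lengths[cat] = np.maximum(lengths[cat], need + 20)

    total_nt = int(sum(arr.sum() for arr in lengths.values()))
    background = _background_codes(total_nt, config.background_AU_fraction, rng)

    utrs: list[UTRRecord] = []
    truth: dict[str, TruthRecord] = {}
    offset = 0
    for cat in _CATEGORIES:
        for i in range(sizes[cat]):
            gene = f"{cat}_{i + 1:05d}"
            L = int(lengths[cat][i])
            codes = background[offset: offset + L].copy()
            offset += L
            planted = [
                (SEVENMER, int(n7[cat][i])),
                (PENTAMER, int(n5x[cat][i])),
                (GAAA, int(ngaaa[cat][i])),
            ]
            _plant_into(codes, planted, rng)
            utrs.append(
                UTRRecord(gene, f"{gene}.t1", codes.tobytes().decode("ascii"))
            )
            truth[gene] = TruthRecord(
                gene, cat, int(n7[cat][i]), int(n5x[cat][i]), int(ngaaa[cat][i])
            )

    de_table: list[DERecord] = []
    for cat in _CATEGORIES:
        n = sizes[cat]
        read_support = np.maximum(10.0, rng.lognormal(math.log(500.0), 1.0, n))
        if cat == "unchanged":
            log2fc = rng.normal(0.0, 0.4, n)
            padj = rng.uniform(0.05, 1.0, n)
        else:
            magnitude = 1.0 + rng.gamma(2.0, (config.effect_log2fc - 1.0) / 2.0, n)
            log2fc = magnitude if cat == "up" else -magnitude
            padj = 10.0 ** (-rng.uniform(1.32, 12.0, n))
        for i in range(n):
            gene = f"{cat}_{i + 1:05d}"
            de_table.append(
                DERecord(
                    gene_id=gene,
                    read_support=float(read_support[i]),
                    log2fc=float(log2fc[i]),
                    padj=float(padj[i]),
                    category=categorize(
                        float(read_support[i]), float(log2fc[i]), float(padj[i])
                    ),
                )
            )

    return SyntheticCohort(utrs=utrs, de_table=de_table, truth=truth, config=config)


def small_config(**overrides) -> SyntheticConfig:
    """A scaled-down configuration convenient for quick runs and tests."""
    base = SyntheticConfig(
        n_up=60,
        n_down=60,
        n_unchanged=300,
        utr_length_median=300.0,
        utr_length_sigma=0.6,
    )
    return replace(base, **overrides)
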
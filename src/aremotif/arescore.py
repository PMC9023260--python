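"""AREScore-like scoring of 3'UTR ARE content.

The score summarises the three classic ARE features: (i) the number of AUUUA
pentamers, (ii) the proximity between pentamers, and (iii) high A/U content
in the vicinity of each pentamer. This is a re-parameterisation of the idea
behind the published AREScore program, not a certified reproduction of its
numbers: the original constants are not public, so every constant here lives
in :class:`AREScoreParams`, defaults are documented implementation choices,
and the parameters in force are serialised into every output.

Scoring rule (all terms additive):

* each pentamer occurrence contributes ``pentamer_weight``;
* each consecutive pentamer pair whose gap (next start minus previous end)
  is at most ``cluster_max_gap`` contributes ``cluster_bonus`` once;
* each pentamer contributes ``au_context_weight`` per flank side (up to two)
  whose ``au_context_window``-nt flank has A/U fraction at least
  ``au_context_min_fraction``. Flanks shorter than the window are evaluated
  on the available bases; an empty flank never qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .motif_scan import PENTAMER, find_motif


@dataclass(frozen=True)
class AREScoreParams:
    pentamer_weight: float = 1.0
    cluster_bonus: float = 1.5
    cluster_max_gap: int = 10
    au_context_weight: float = 0.5
    au_context_window: int = 5
    au_context_min_fraction: float = 0.8

    def validate(self) -> None:
        if min(self.pentamer_weight, self.cluster_bonus, self.au_context_weight) < 0:
            raise ValueError("all weights must be >= 0")
        if not 0.0 <= self.au_context_min_fraction <= 1.0:
            raise ValueError("au_context_min_fraction must be in [0, 1]")
        if self.au_context_window < 0:
            raise ValueError("au_context_window must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class AREScoreResult:
    gene_id: str
    score: float
    n_pentamers: int
    n_cluster_bonuses: int
    n_context_bonuses: int


def _au_fraction(flank: str) -> float:
    if not flank:
        return 0.0
    return sum(c in "AU" for c in flank) / len(flank)


def arescore(
    sequence: str, params: AREScoreParams | None = None, gene_id: str = ""
) -> AREScoreResult:
    """Score one sequence for ARE content under ``params``.

    The score is exactly ``pentamer_weight * n_pentamers + cluster_bonus *
    n_cluster_bonuses + au_context_weight * n_context_bonuses`` and is zero
    iff the sequence contains no AUUUA.
    """
    if params is None:
        params = AREScoreParams()
    params.validate()

    hits = find_motif(sequence, PENTAMER)
    n_cluster = sum(
        1 for a, b in zip(hits, hits[1:]) if b.start - a.end <= params.cluster_max_gap
    )
    n_context = 0
    w = params.au_context_window
    for h in hits:
        left = sequence[max(0, h.start - w): h.start]
        right = sequence[h.end: h.end + w]
        for flank in (left, right):
            if flank and _au_fraction(flank) >= params.au_context_min_fraction:
                n_context += 1

    score = (
        params.pentamer_weight * len(hits)
        + params.cluster_bonus * n_cluster
        + params.au_context_weight * n_context
    )
    return AREScoreResult(
        gene_id=gene_id,
        score=score,
        n_pentamers=len(hits),
        n_cluster_bonuses=n_cluster,
        n_context_bonuses=n_context,
    )


def write_arescore_tsv(results, path, params: AREScoreParams | None = None, *, header_lines=()):
    """Write scores as TSV, echoing the parameters as comment lines."""
    if params is None:
        params = AREScoreParams()
    with open(path, "w") as handle:
        for line in header_lines:
            handle.write(f"# {line}\n")
        for key, value in params.as_dict().items():
            handle.write(f"# param {key} = {value}\n")
        handle.write(
            "gene_id\tscore\tn_pentamers\tn_cluster_bonuses\tn_context_bonuses\n"
        )
        for r in results:
            handle.write(
                f"{r.gene_id}\t{r.score!r}\t{r.n_pentamers}\t"
                f"{r.n_cluster_bonuses}\t{r.n_context_bonuses}\n"
            )
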
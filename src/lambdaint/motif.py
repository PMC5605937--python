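"""Integration-site motif: matrix building, scoring, and genome-wide scan.

The motif window is 29 bases read on the integration strand, registered so
label 0 is the first base of the 7-nt strand-exchange region (labels -14..+14
by default, configurable). Scores are log2-odds sums against a background
composition; the genome scan provides the all-29-mer baseline and the
high-score-but-undetected window list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import Genome, revcomp
from .site_caller import SiteCatalog, frequency_class

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class InsufficientDataError(ValueError):
    """Raised when too few windows are available to build a matrix."""


@dataclass
class MotifWindow:
    site_id: str
    sequence: str  # read on the integration strand
    offset_left: int = 14
    offset_right: int = 14

    @property
    def labels(self) -> range:
        return range(-self.offset_left, self.offset_right + 1)


@dataclass
class PositionScoringMatrix:
    counts: np.ndarray  # width x 4 integer counts
    frequencies: np.ndarray  # width x 4, pseudocount-adjusted, rows sum to 1
    log_odds: np.ndarray  # width x 4, log2(freq / background)
    background: dict[str, float]
    pseudocount: float
    information_content: np.ndarray = field(default=None)  # bits per position
    offset_left: int = 14

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def to_meme(self, path: str | Path, name: str = "integration_site") -> None:
        """Minimal MEME motif format export."""
        bg = self.background
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "Background letter frequencies",
            f"A {bg['A']:.5f} C {bg['C']:.5f} G {bg['G']:.5f} T {bg['T']:.5f}",
            "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width} "
            f"nsites= {int(self.counts[0].sum())} E= 0",
        ]
        for row in self.frequencies:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def extract_windows(
    genome: Genome,
    catalog: SiteCatalog,
    offset_left: int = 14,
    offset_right: int = 14,
) -> list[MotifWindow]:
    """Window around each site, read on the integration strand.

    '+' sites take genome[pos-offset_left .. pos+offset_right]; '-' sites take
    the reverse complement of the mirrored interval, so a '+' and a '-' site
    planted with the same window yield identical strings. Windows off a linear
    genome end are skipped with a warning (never happens on circular genomes).
    """
    width = offset_left + offset_right + 1
    windows = []
    for site in catalog.sites:
        pos0 = site.position - 1
        start = pos0 - offset_left if site.strand == "+" else pos0 - offset_right
        try:
            seq = genome.fetch(start, width)
        except IndexError:
            logger.warning("site %s: window off linear genome end, skipped", site.site_id)
            continue
        if site.strand == "-":
            seq = revcomp(seq)
        windows.append(MotifWindow(site.site_id, seq, offset_left, offset_right))
    return windows


def build_matrix(
    windows: list[MotifWindow] | list[str],
    pseudocount: float = 1.0,
    background: dict[str, float] | None = None,
    offset_left: int = 14,
) -> PositionScoringMatrix:
    """Tally per-position base counts and derive frequencies/log-odds/IC.

    frequencies = (count + pseudocount) / (n + 4*pseudocount);
    information_content = 2 + sum_b f*log2(f) bits. Windows containing N are
    excluded from the tally.
    """
    seqs = [w.sequence if isinstance(w, MotifWindow) else w for w in windows]
    seqs = [s for s in seqs if "N" not in s]
    if len(seqs) < 2:
        raise InsufficientDataError(f"need >= 2 N-free windows, got {len(seqs)}")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("windows have inconsistent widths")
    if isinstance(windows[0], MotifWindow):
        offset_left = windows[0].offset_left
    counts = np.zeros((width, 4), dtype=np.int64)
    for s in seqs:
        for j, b in enumerate(s):
            counts[j, _BASE_INDEX[b]] += 1
    n = len(seqs)
    freqs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    if background is None:
        background = {b: 0.25 for b in BASES}
    bg = np.array([background[b] for b in BASES], dtype=float)
    if (bg <= 0).any():
        raise ValueError("background frequencies must be positive")
    with np.errstate(divide="ignore"):
        log_odds = np.log2(freqs / bg)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    return PositionScoringMatrix(
        counts=counts,
        frequencies=freqs,
        log_odds=log_odds,
        background=dict(background),
        pseudocount=pseudocount,
        information_content=ic,
        offset_left=offset_left,
    )


def score_sequence(matrix: PositionScoringMatrix, window: str) -> float:
    """Sum of per-position log-odds; NaN marks windows containing N."""
    if len(window) != matrix.width:
        raise ValueError(f"window length {len(window)} != matrix width {matrix.width}")
    if "N" in window:
        return math.nan
    lo = matrix.log_odds
    return float(sum(lo[j, _BASE_INDEX[b]] for j, b in enumerate(window)))


@dataclass
class ScanSummary:
    mean: float
    sd: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    n_windows: int
    top_undetected: list[tuple[int, str, float]]  # (0-based window start, strand, score)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)  # N and anything else -> 4
    for b, i in _BASE_INDEX.items():
        codes[arr == ord(b)] = i
    return codes


def scan_genome(
    matrix: PositionScoringMatrix,
    genome: Genome,
    catalog: SiteCatalog | None = None,
    top_k: int = 10,
    n_bins: int = 50,
) -> ScanSummary:
    """Score every window start on both strands (circular-aware).

    Reports the all-window mean (the genome-wide baseline), the score
    histogram, and the ``top_k`` highest-scoring windows that do not
    correspond to a cataloged site. Windows containing N are excluded.
    """
    w = matrix.width
    L = len(genome)
    if genome.circular:
        codes = _encode(genome.sequence + genome.sequence[: w - 1])
        n_starts = L
    else:
        codes = _encode(genome.sequence)
        n_starts = L - w + 1
    win = np.lib.stride_tricks.sliding_window_view(codes, w)[:n_starts]

    # 5-row lookup per column; row 4 (N) poisons the window with NaN
    def strand_scores(lo: np.ndarray) -> np.ndarray:
        lut = np.vstack([lo.T, np.full((1, w), np.nan)])  # 5 x w
        return lut[win, np.arange(w)].sum(axis=1)

    fwd = strand_scores(matrix.log_odds)
    rc_lo = matrix.log_odds[::-1, ::-1]  # reverse-complement matrix
    rev = strand_scores(rc_lo)

    detected: set[tuple[int, str]] = set()
    if catalog is not None:
        ol = matrix.offset_left
        orr = w - 1 - ol
        for site in catalog.sites:
            pos0 = site.position - 1
            if site.strand == "+":
                detected.add(((pos0 - ol) % L, "+"))
            else:
                detected.add(((pos0 - orr) % L, "-"))

    all_scores = np.concatenate([fwd, rev])
    valid = all_scores[~np.isnan(all_scores)]
    mean = float(valid.mean())
    sd = float(valid.std())
    counts, edges = np.histogram(valid, bins=n_bins)

    candidates: list[tuple[float, int, str]] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        order = np.argsort(scores)
        take = order[~np.isnan(scores[order])][::-1][: top_k + len(detected)]
        for idx in take:
            if (int(idx), strand) not in detected:
                candidates.append((float(scores[idx]), int(idx), strand))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    top = [(start, strand, score) for score, start, strand in candidates[:top_k]]

    return ScanSummary(
        mean=mean,
        sd=sd,
        histogram_counts=counts,
        histogram_edges=edges,
        n_windows=int(valid.size),
        top_undetected=top,
    )


def relative_scores(
    matrix: PositionScoringMatrix,
    catalog: SiteCatalog,
    genome: Genome,
    offset_left: int = 14,
    offset_right: int = 14,
) -> SiteCatalog:
    """Fill motif_score and relative_score (score minus catalog mean) in place.

    The relative scores of scored sites average to zero; ordering by relative
    score equals ordering by raw score.
    """
    windows = {w.site_id: w for w in extract_windows(genome, catalog, offset_left, offset_right)}
    scored: list[float] = []
    for site in catalog.sites:
        w = windows.get(site.site_id)
        if w is None:
            site.motif_score = None
            continue
        s = score_sequence(matrix, w.sequence)
        site.motif_score = None if math.isnan(s) else s
        if site.motif_score is not None:
            scored.append(site.motif_score)
    center = float(np.mean(scored)) if scored else 0.0
    for site in catalog.sites:
        site.relative_score = (
            site.motif_score - center if site.motif_score is not None else None
        )
    return catalog


def score_by_detection_frequency(catalog: SiteCatalog) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group mean motif score by detection frequency.

    Returns (per-frequency table, display-class table with groups 1 / 2-4 / >4).
    Group sizes partition the scored catalog.
    """
    rows = [
        {
            "detection_frequency": s.detection_frequency,
            "score": s.motif_score,
        }
        for s in catalog.sites
        if s.motif_score is not None
    ]
    df = pd.DataFrame(rows, columns=["detection_frequency", "score"])
    if df.empty:
        empty = pd.DataFrame(columns=["group", "mean_score", "n"])
        return empty.copy(), empty.copy()
    per_freq = (
        df.groupby("detection_frequency")["score"]
        .agg(mean_score="mean", n="size")
        .reset_index()
        .rename(columns={"detection_frequency": "group"})
    )
    df["cls"] = df["detection_frequency"].map(frequency_class)
    order = [label for label, _, _ in (("1", 1, 1), ("2-4", 2, 4), (">4", 5, 0))]
    per_class = (
        df.groupby("cls")["score"].agg(mean_score="mean", n="size").reindex(order).dropna(
            how="all"
        )
    )
    per_class = per_class.reset_index().rename(columns={"cls": "group"})
    per_class["n"] = per_class["n"].astype(int)
    return per_freq, per_class
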
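"""Sliding-window heterozygosity tracks and run-of-homozygosity calling.

Each chromosome is tiled with overlapping windows (default 1 Mbp windows
advanced in 2 kbp steps, anchored at 0) and the number of heterozygous
genotypes of the target sample per window is converted to a het/kbp
density. ROH segments are called in two stages: maximal runs of windows
below a density threshold (default 0.1 het/kbp) locate candidate regions,
whose boundaries are then refined to the span of zero-heterozygote windows
within the run — the window track smears a true boundary by up to one
window length, while the zero-het core pins it to within one step of the
nearest flanking heterozygous site. Runs shorter than a minimum length
(default 1 Mbp) are dropped.

A per-chromosome plot of the track (y fixed to 0-3 het/kbp) is provided so
the calls can also be inspected visually.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .variant_io import VariantSite

__all__ = [
    "WindowHeterozygosity",
    "ROHSegment",
    "window_heterozygosity",
    "call_roh",
    "genome_wide_heterozygosity",
    "write_bedgraph",
    "write_roh_bed",
    "plot_heterozygosity",
]


@dataclass(frozen=True)
class WindowHeterozygosity:
    """Heterozygote density of one sample in one window [start, end)."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    het_count: int

    @property
    def het_per_kbp(self) -> float:
        return self.het_count * 1000.0 / (self.end - self.start)


@dataclass(frozen=True)
class ROHSegment:
    """A called run of homozygosity [start, end), 0-based half-open."""

    chrom: str
    start: int
    end: int
    mean_het_per_kbp: float
    n_windows: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _het_positions_by_chrom(
    sample_id: str, sites: Iterable[VariantSite]
) -> Dict[str, np.ndarray]:
    """0-based positions of the sample's heterozygous genotypes, per
    chromosome; enforces (chrom, pos) sort order of the input."""
    positions: Dict[str, List[int]] = {}
    seen_chroms: List[str] = []
    last: Optional[Tuple[str, int]] = None
    for site in sites:
        if last is not None and site.chrom == last[0] and site.pos < last[1]:
            raise ValueError(
                f"input not sorted: {site.chrom}:{site.pos} after {last[0]}:{last[1]}"
            )
        if site.chrom not in positions:
            if site.chrom in seen_chroms:
                raise ValueError(f"input not sorted: chromosome {site.chrom} recurs")
            positions[site.chrom] = []
            seen_chroms.append(site.chrom)
        last = (site.chrom, site.pos)
        if site.genotype_of(sample_id).is_het:
            positions[site.chrom].append(site.pos - 1)
    return {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()}


def window_heterozygosity(
    sample_id: str,
    sites: Iterable[VariantSite],
    window: int = 1_000_000,
    step: int = 2_000,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> List[WindowHeterozygosity]:
    """Heterozygosity track of one sample over sliding windows.

    Windows start at offsets 0, step, 2*step, ... per chromosome; terminal
    windows are truncated to the chromosome end and emitted with their true
    length. ``chrom_lengths`` defaults to the last observed site position
    per chromosome. Input must be sorted by (chrom, pos).
    """
    if step <= 0 or window <= 0 or step > window:
        raise ValueError(f"need 0 < step <= window, got step={step} window={window}")
    het = _het_positions_by_chrom(sample_id, sites)
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(p[-1]) + 1 if len(p) else 1 for c, p in het.items()
        }
    unknown = set(het) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"sites on chromosome(s) absent from chrom_lengths: {sorted(unknown)}")

    out: List[WindowHeterozygosity] = []
    for chrom, length in chrom_lengths.items():
        pos = het.get(chrom, np.empty(0, dtype=np.int64))
        starts = np.arange(0, max(length, 1), step, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        counts = np.searchsorted(pos, ends, side="left") - np.searchsorted(
            pos, starts, side="left"
        )
        for s, e, c in zip(starts, ends, counts):
            if e > s:
                out.append(WindowHeterozygosity(chrom, int(s), int(e), int(c)))
    return out


def call_roh(
    windows: Sequence[WindowHeterozygosity],
    het_threshold: float = 0.1,
    min_length: int = 1_000_000,
) -> List[ROHSegment]:
    """Call ROH segments from one sample's window track.

    Candidate segments are maximal runs of consecutive windows with
    het_per_kbp strictly below ``het_threshold``; each candidate's bounds
    are refined to the span of its zero-heterozygote windows (when any
    exist) to undo the one-window boundary smearing of the coarse track.
    Refined segments shorter than ``min_length`` are dropped.
    """
    by_chrom: Dict[str, List[WindowHeterozygosity]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)

    segments: List[ROHSegment] = []
    for chrom, ws in by_chrom.items():
        ws = sorted(ws, key=lambda w: w.start)
        run: List[WindowHeterozygosity] = []
        for w in ws + [None]:  # sentinel flushes the last run
            if w is not None and w.het_per_kbp < het_threshold:
                run.append(w)
                continue
            if run:
                seg = _refine_run(chrom, run)
                if seg is not None and seg.length >= min_length:
                    segments.append(seg)
                run = []
    return sorted(segments, key=lambda s: (s.chrom, s.start))


def _refine_run(
    chrom: str, run: List[WindowHeterozygosity]
) -> Optional[ROHSegment]:
    zero = [w for w in run if w.het_count == 0]
    core = zero if zero else run
    start = core[0].start
    end = max(w.end for w in core)
    n = sum(1 for w in run if w.start >= start and w.end <= end) or len(core)
    kept = [w for w in run if start <= w.start and w.end <= end] or core
    mean_het = float(np.mean([w.het_per_kbp for w in kept]))
    return ROHSegment(
        chrom=chrom, start=start, end=end, mean_het_per_kbp=mean_het, n_windows=n
    )


def genome_wide_heterozygosity(
    sample_id: str, sites: Iterable[VariantSite], mappable_length: int
) -> float:
    """Genome-wide heterozygosity of one sample in het sites per kbp of
    mappable genome."""
    if mappable_length <= 0:
        raise ValueError(f"mappable_length must be > 0, got {mappable_length}")
    n_het = sum(1 for s in sites if s.genotype_of(sample_id).is_het)
    return n_het * 1000.0 / mappable_length


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_bedgraph(windows: Sequence[WindowHeterozygosity], path) -> None:
    """Write the track as bedGraph (chrom, start, end, het_per_kbp)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="het_per_kbp"\n')
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.het_per_kbp:.6g}\n")


def write_roh_bed(segments: Sequence[ROHSegment], path) -> None:
    """Write ROH calls as BED3+score (score = mean het/kbp)."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.mean_het_per_kbp:.6g}\n")


def plot_heterozygosity(
    windows: Sequence[WindowHeterozygosity],
    out_dir,
    sample_id: str = "",
    ylim: Tuple[float, float] = (0.0, 3.0),
    segments: Optional[Sequence[ROHSegment]] = None,
) -> List[Path]:
    """One PNG per chromosome: het/kbp vs position, y fixed to ``ylim``;
    called ROH segments, when given, are shaded. Returns written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_chrom: Dict[str, List[WindowHeterozygosity]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    paths: List[Path] = []
    for chrom, ws in by_chrom.items():
        ws = sorted(ws, key=lambda w: w.start)
        fig, ax = plt.subplots(figsize=(10, 2.2))
        ax.plot(
            [(w.start + w.end) / 2e6 for w in ws],
            [w.het_per_kbp for w in ws],
            lw=0.6,
            color="#1f77b4",
        )
        for seg in segments or []:
            if seg.chrom == chrom:
                ax.axvspan(seg.start / 1e6, seg.end / 1e6, color="red", alpha=0.25)
        ax.set_ylim(*ylim)
        ax.set_xlabel(f"{chrom} position (Mbp)")
        ax.set_ylabel("het / kbp")
        title = f"{sample_id} {chrom}".strip()
        ax.set_title(title)
        fig.tight_layout()
        path = out_dir / f"het_{chrom}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
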
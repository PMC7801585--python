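"""Windowed GC scan with bimodality summary, and domain expansion indexing.

AT-rich parasitoid genomes can carry scattered windows of much lower GC
than the genomic background (foreign-origin islands); the scan computes
per-window GC = (G+C)/(A+C+G+T) over non-overlapping windows and
summarizes the distribution's modes by kernel density estimation. Domain
expansion compares a focal species' domain counts against the maximum in
all comparison species; a domain present only in the focal species is
"exclusive" (a tagged category, never a floating-point infinity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .formats_io import DomainCountTable, SequenceRecord

__all__ = [
    "GcWindow",
    "GcWindowTrack",
    "GcMode",
    "DomainExpansionReport",
    "gc_windows",
    "gc_mode_summary",
    "expansion_index",
]


@dataclass(frozen=True)
class GcWindow:
    start: int
    end: int
    gc: float        # nan when masked
    masked: bool     # > 50% N


@dataclass
class GcWindowTrack:
    window: int
    step: int
    windows: list[GcWindow]

    def gc_values(self) -> np.ndarray:
        return np.array([w.gc for w in self.windows if not w.masked])


def gc_windows(genome: SequenceRecord | str,
               window: int = 10000,
               step: int = 10000) -> GcWindowTrack:
    """Per-window GC fractions over a sequence.

    GC = (G+C)/(A+C+G+T); windows with more than 50% N are flagged and
    excluded from summaries. The trailing partial window is kept when at
    least ``window`` bases long (i.e. only full windows are emitted).
    """
    seq = (genome.residues if isinstance(genome, SequenceRecord)
           else genome).upper()
    if window < 100:
        raise ValueError("window must be at least 100 bp")
    if len(seq) < window:
        raise ValueError("sequence shorter than one window")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_at = (arr == ord("A")) | (arr == ord("T"))
    is_n = ~(is_gc | is_at)
    out: list[GcWindow] = []
    for start in range(0, len(seq) - window + 1, step):
        end = start + window
        n_n = int(is_n[start:end].sum())
        if n_n > window / 2:
            out.append(GcWindow(start, end, math.nan, True))
            continue
        gc = int(is_gc[start:end].sum())
        at = int(is_at[start:end].sum())
        denom = gc + at
        out.append(GcWindow(start, end, gc / denom if denom else math.nan,
                            denom == 0))
    return GcWindowTrack(window=window, step=step, windows=out)


@dataclass(frozen=True)
class GcMode:
    location: float
    mass: float      # fraction of windows assigned to this mode
    density: float


def gc_mode_summary(track: GcWindowTrack,
                    bandwidth: float = 0.02,
                    min_separation: float = 0.05,
                    min_windows: int = 50) -> list[GcMode]:
    """Modes of the window-GC distribution by KDE peak finding.

    A Gaussian KDE with absolute bandwidth ``bandwidth`` is evaluated on
    [0, 1]; local maxima separated by at least ``min_separation`` are
    reported with their mass (fraction of windows nearest to each mode).
    Modes are ordered by mass then location; the primary mode comes first.
    """
    vals = track.gc_values()
    if vals.size < min_windows:
        raise ValueError(f"only {vals.size} unmasked windows "
                         f"(need ≥ {min_windows})")
    sd = vals.std()
    if sd == 0:
        return [GcMode(location=float(vals[0]), mass=1.0, density=math.inf)]
    kde = gaussian_kde(vals, bw_method=bandwidth / sd)
    grid = np.linspace(0.0, 1.0, 1001)
    dens = kde(grid)
    # local maxima (plateau-safe on the discrete grid)
    peaks = [i for i in range(1, len(grid) - 1)
             if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]]
    # enforce separation: keep the highest peaks greedily
    kept: list[int] = []
    for i in sorted(peaks, key=lambda i: -dens[i]):
        if all(abs(grid[i] - grid[j]) >= min_separation for j in kept):
            kept.append(i)
    locations = np.array(sorted(grid[i] for i in kept))
    # mass: assign each window to the nearest mode
    assign = np.argmin(np.abs(vals[:, None] - locations[None, :]), axis=1)
    modes = []
    for m, loc in enumerate(locations):
        mass = float(np.mean(assign == m))
        modes.append(GcMode(location=float(loc), mass=mass,
                            density=float(kde(loc)[0])))
    modes.sort(key=lambda md: (-md.mass, md.location))
    return modes


@dataclass
class DomainExpansionReport:
    """Per-domain expansion/contraction of the focal species."""

    focal_species: str
    table: pd.DataFrame
    # columns: focal_count, max_other, expansion_index, contraction_index
    # with "exclusive" / "exclusive-elsewhere" tags as strings


def expansion_index(domain_counts: DomainCountTable,
                    focal_species: str) -> DomainExpansionReport:
    """Expansion index per domain: focal count / max count in all other
    species.

    Tagged categories: "exclusive" when all others are 0 but the focal
    count is positive; contraction index is the symmetric ratio, with
    "exclusive-elsewhere" when the focal count is 0 and some other
    species has the domain.
    """
    df = domain_counts.counts
    if focal_species not in df.columns:
        raise KeyError(f"focal species {focal_species!r} not in table")
    others = [c for c in df.columns if c != focal_species]
    if not others:
        raise ValueError("need at least 2 species columns")
    rows = []
    for dom in df.index:
        focal = int(df.at[dom, focal_species])
        mx = int(df.loc[dom, others].max())
        if focal > 0 and mx == 0:
            ei: float | str = "exclusive"
        elif focal == 0:
            ei = 0.0
        else:
            ei = focal / mx
        if mx > 0 and focal == 0:
            ci: float | str = "exclusive-elsewhere"
        elif mx == 0:
            ci = 0.0
        else:
            ci = mx / focal
        rows.append((dom, focal, mx, ei, ci))
    table = pd.DataFrame(rows, columns=["domain_id", "focal_count",
                                        "max_other", "expansion_index",
                                        "contraction_index"]
                         ).set_index("domain_id")
    return DomainExpansionReport(focal_species=focal_species, table=table)
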
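"""HCR split-probe candidate enumeration and selection.

Split-initiator probe pairs tile a transcript as windows of two half-sites
(default 25 nt each, HCR v3.0 convention) separated by a short gap (2 nt).
Candidates start after a 5' skip (100 bp, when transcript length permits) and
are filtered on homopolymer runs (polyA/T <= 5, polyC/G <= 4), per-half GC
content (45-60%) and the GC difference between the two halves (<= 6
percentage points).  Selection picks a spaced subset maximizing the minimum
inter-pair distance.  Off-target screening (BLAST) is out of scope; the
FASTA export hook feeds external screens.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

FILTER_NAMES = ("polyAT", "polyCG", "gc_range", "gc_diff")


@dataclass
class ProbeConfig:
    skip_5prime: int = 100
    half_site_length: int = 25
    gap: int = 2
    max_polyAT_run: int = 5
    max_polyCG_run: int = 4
    gc_min: float = 45.0
    gc_max: float = 60.0
    max_gc_difference: float = 6.0
    pairs_per_gene: tuple[int, int] = (5, 11)
    min_spacing: int = 0

    def __post_init__(self):
        if self.half_site_length <= 0 or self.gap < 0:
            raise ValueError("half_site_length must be > 0 and gap >= 0")
        if not (0 <= self.gc_min <= self.gc_max <= 100):
            raise ValueError("GC bounds must satisfy 0 <= min <= max <= 100")

    @property
    def window(self) -> int:
        return 2 * self.half_site_length + self.gap


@dataclass
class ProbePair:
    transcript_id: str
    start: int                    # window start, transcript coordinate (0-based)
    half1: str
    half2: str
    gc1: float
    gc2: float
    flags: dict[str, bool] = field(default_factory=dict)  # True = passes

    @property
    def passes(self) -> bool:
        return all(self.flags.values())


def gc_content(seq: str) -> float:
    return 100.0 * sum(c in "GC" for c in seq) / len(seq) if seq else 0.0


def max_run(seq: str, alphabet: str) -> int:
    """Longest run of consecutive characters drawn from ``alphabet``."""
    best = run = 0
    for c in seq:
        run = run + 1 if c in alphabet else 0
        best = max(best, run)
    return best


def enumerate_candidates(sequence: str, transcript_id: str = "tx",
                         config: ProbeConfig | None = None) -> list[ProbePair]:
    """All sliding-window probe-pair candidates with per-filter flags.

    Windows start at ``skip_5prime`` (or at 0 when the sequence is shorter
    than skip + window, mirroring the when-length-permits rule; a sequence
    shorter than one window yields an empty list with a warning).
    """
    config = config or ProbeConfig()
    seq = sequence.upper()
    if not re.fullmatch("[ACGT]*", seq):
        raise ValueError("sequence must be over ACGT")
    w = config.window
    skip = config.skip_5prime if len(seq) > config.skip_5prime + w else 0
    if len(seq) < w:
        warnings.warn(f"{transcript_id}: sequence shorter than one probe window")
        return []
    out = []
    h = config.half_site_length
    for start in range(skip, len(seq) - w + 1):
        half1 = seq[start:start + h]
        half2 = seq[start + h + config.gap:start + w]
        window_seq = seq[start:start + w]
        gc1, gc2 = gc_content(half1), gc_content(half2)
        flags = {
            "polyAT": max_run(window_seq, "AT") <= config.max_polyAT_run,
            "polyCG": max_run(window_seq, "CG") <= config.max_polyCG_run,
            "gc_range": (config.gc_min <= gc1 <= config.gc_max
                         and config.gc_min <= gc2 <= config.gc_max),
            "gc_diff": abs(gc1 - gc2) <= config.max_gc_difference,
        }
        out.append(ProbePair(transcript_id, start, half1, half2, gc1, gc2, flags))
    return out


def select_module_set(candidates: list[ProbePair], n_pairs: int,
                      config: ProbeConfig | None = None) -> list[ProbePair]:
    """Pick ``n_pairs`` passing candidates maximizing the minimum spacing.

    Deterministic: binary search on the spacing with a leftmost-greedy
    feasibility check, then the lexicographically earliest optimal placement.
    Non-overlapping by construction (spacing never below the window length).
    If fewer passing candidates exist than requested, all are returned with a
    warning; zero passing candidates is an error.
    """
    config = config or ProbeConfig()
    passing = sorted((c for c in candidates if c.passes), key=lambda c: c.start)
    if not passing:
        raise ValueError("no passing probe candidates")
    if len(passing) <= n_pairs:
        if len(passing) < n_pairs:
            warnings.warn(
                f"only {len(passing)} passing candidates for {n_pairs} requested")
        return passing

    starts = [c.start for c in passing]
    floor_gap = max(config.window, config.min_spacing)

    def greedy(min_gap: int) -> list[int] | None:
        chosen = [0]
        for i in range(1, len(starts)):
            if starts[i] - starts[chosen[-1]] >= min_gap:
                chosen.append(i)
                if len(chosen) == n_pairs:
                    return chosen
        return None

    lo, hi = floor_gap, starts[-1] - starts[0]
    best = greedy(lo)
    if best is None:
        raise ValueError(
            f"cannot place {n_pairs} non-overlapping pairs at spacing {floor_gap}")
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if greedy(mid) is not None:
            lo = mid
        else:
            hi = mid - 1
    return [passing[i] for i in greedy(lo)]


def probe_sheet(pairs: list[ProbePair]) -> pd.DataFrame:
    """Order-sheet style table (one row per half-site)."""
    rows = []
    for p in sorted(pairs, key=lambda c: (c.transcript_id, c.start)):
        base = f"{p.transcript_id}_{p.start + 1}"
        rows.append({"name": base + "_A", "transcript_id": p.transcript_id,
                     "window_start": p.start, "half": "A", "sequence": p.half1,
                     "gc_percent": round(p.gc1, 2)})
        rows.append({"name": base + "_B", "transcript_id": p.transcript_id,
                     "window_start": p.start, "half": "B", "sequence": p.half2,
                     "gc_percent": round(p.gc2, 2)})
    return pd.DataFrame(rows)


def export_fasta(pairs: list[ProbePair], path) -> None:
    """FASTA of candidate half-sites for external off-target screening."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.transcript_id}_{p.start + 1}_A\n{p.half1}\n")
            fh.write(f">{p.transcript_id}_{p.start + 1}_B\n{p.half2}\n")
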
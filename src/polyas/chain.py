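"""UCSC chain files and interval liftover between wheat subgenomes.

A chain describes a gapped pairwise alignment between a *source* genome (the
``t`` side of the UCSC header, the genome intervals are expressed in) and a
*target* genome (the ``q`` side, the genome they are mapped to).  Block lines
``size dt dq`` give the aligned block length and the gaps that follow it on
the source (dt) and target (dq) side.  Coordinates are 0-based half-open; a
negative target strand is handled per the UCSC convention (coordinates on the
reversed strand, flipped back to forward on output).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Chain:
    score: int
    s_name: str
    s_size: int
    s_strand: str
    s_start: int
    s_end: int
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    chain_id: int
    sizes: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    dt: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))  # source gaps
    dq: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))  # target gaps

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.dt = np.asarray(self.dt, dtype=np.int64)
        self.dq = np.asarray(self.dq, dtype=np.int64)
        if len(self.dt) != len(self.sizes) - 1 or len(self.dq) != len(self.sizes) - 1:
            raise ValueError(f"chain {self.chain_id}: need exactly one gap pair between blocks")
        if (self.sizes <= 0).any() or (self.dt < 0).any() or (self.dq < 0).any():
            raise ValueError(f"chain {self.chain_id}: block sizes and gaps must be non-negative")
        if self.s_strand != "+":
            raise ValueError(f"chain {self.chain_id}: source strand must be '+'")
        s_span = int(self.sizes.sum() + self.dt.sum())
        t_span = int(self.sizes.sum() + self.dq.sum())
        if s_span != self.s_end - self.s_start:
            raise ValueError(f"chain {self.chain_id}: source span mismatch")
        if t_span != self.t_end - self.t_start:
            raise ValueError(f"chain {self.chain_id}: target span mismatch")

    def blocks(self) -> list[tuple[int, int, int, int]]:
        """Aligned blocks as (s_start, s_end, t_start, t_end) in strand coords."""
        out = []
        s, t = self.s_start, self.t_start
        for i, size in enumerate(self.sizes):
            out.append((s, s + int(size), t, t + int(size)))
            s += int(size)
            t += int(size)
            if i < len(self.sizes) - 1:
                s += int(self.dt[i])
                t += int(self.dq[i])
        return out

    def invert(self) -> "Chain":
        """Swap source and target, producing the inverse mapping.

        Only defined for '+'/'+' chains (the synthetic chains this package
        emits are colinear by default).
        """
        if self.t_strand != "+":
            raise ValueError("cannot invert a chain with a negative target strand")
        return Chain(
            score=self.score,
            s_name=self.t_name, s_size=self.t_size, s_strand="+",
            s_start=self.t_start, s_end=self.t_end,
            t_name=self.s_name, t_size=self.s_size, t_strand="+",
            t_start=self.s_start, t_end=self.s_end,
            chain_id=self.chain_id,
            sizes=self.sizes.copy(), dt=self.dq.copy(), dq=self.dt.copy(),
        )


def read_chain(path: str | Path) -> list[Chain]:
    chains: list[Chain] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("chain "):
            raise ValueError(f"expected chain header at line {i + 1}, got {line!r}")
        parts = line.split()
        if len(parts) != 13:
            raise ValueError(f"malformed chain header at line {i + 1}")
        (_, score, s_name, s_size, s_strand, s_start, s_end,
         t_name, t_size, t_strand, t_start, t_end, cid) = parts
        sizes, dts, dqs = [], [], []
        i += 1
        while i < len(lines) and lines[i].strip():
            fields = lines[i].split()
            if len(fields) == 3:
                sizes.append(int(fields[0]))
                dts.append(int(fields[1]))
                dqs.append(int(fields[2]))
            elif len(fields) == 1:
                sizes.append(int(fields[0]))
                i += 1
                break
            else:
                raise ValueError(f"malformed block line at line {i + 1}")
            i += 1
        if len(sizes) == 0 or len(dts) != len(sizes) - 1:
            raise ValueError(f"chain {cid}: malformed block count")
        chains.append(
            Chain(
                score=int(score),
                s_name=s_name, s_size=int(s_size), s_strand=s_strand,
                s_start=int(s_start), s_end=int(s_end),
                t_name=t_name, t_size=int(t_size), t_strand=t_strand,
                t_start=int(t_start), t_end=int(t_end),
                chain_id=int(cid), sizes=sizes, dt=dts, dq=dqs,
            )
        )
    return chains


def write_chain(chains: list[Chain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score} {c.s_name} {c.s_size} {c.s_strand} "
                f"{c.s_start} {c.s_end} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.chain_id}\n"
            )
            for i, size in enumerate(c.sizes):
                if i < len(c.sizes) - 1:
                    fh.write(f"{int(size)} {int(c.dt[i])} {int(c.dq[i])}\n")
                else:
                    fh.write(f"{int(size)}\n")
            fh.write("\n")


class ChainSet:
    """Chains from one source genome to one target genome, indexed by source chromosome.

    Chains must be pairwise non-overlapping on the source so every source
    interval has at most one mapping (the 1:1 orthology use case).
    """

    def __init__(self, chains: list[Chain]):
        self.chains = list(chains)
        self._by_chrom: dict[str, list[Chain]] = {}
        for c in self.chains:
            self._by_chrom.setdefault(c.s_name, []).append(c)
        for chrom, cs in self._by_chrom.items():
            cs.sort(key=lambda c: c.s_start)
            for a, b in zip(cs, cs[1:]):
                if b.s_start < a.s_end:
                    raise ValueError(f"chains overlap on source {chrom}: ids {a.chain_id}, {b.chain_id}")

    def invert(self) -> "ChainSet":
        return ChainSet([c.invert() for c in self.chains])

    def liftover(
        self, chrom: str, start: int, end: int, min_overlap_fraction: float = 0.5
    ) -> tuple[str, int, int, str] | None:
        """Map a source interval to the target genome.

        Returns ``(chrom, start, end, strand)`` on the forward strand of the
        target, or ``None`` when less than ``min_overlap_fraction`` of the
        interval's bases fall into aligned blocks.
        """
        if start >= end or start < 0:
            raise ValueError(f"bad interval [{start}, {end})")
        for c in self._by_chrom.get(chrom, []):
            if c.s_size and end > c.s_size:
                raise ValueError(f"interval [{start}, {end}) beyond chromosome {chrom} bounds")
            if end <= c.s_start or start >= c.s_end:
                continue
            mapped = []  # pieces in target strand coords
            aligned = 0
            for bs, be, ts, te in c.blocks():
                lo, hi = max(start, bs), min(end, be)
                if lo < hi:
                    aligned += hi - lo
                    mapped.append((ts + (lo - bs), ts + (hi - bs)))
            if not mapped or aligned / (end - start) < min_overlap_fraction:
                return None
            q_lo = min(m[0] for m in mapped)
            q_hi = max(m[1] for m in mapped)
            if c.t_strand == "-":
                q_lo, q_hi = c.t_size - q_hi, c.t_size - q_lo
            return c.t_name, q_lo, q_hi, c.t_strand
        return None
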
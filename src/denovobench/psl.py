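"""BLAT PSL alignment records: parsing, validation and writing.

PSL is BLAT's native tab-separated output: 21 columns of match/mismatch/gap
counts, strand, query/target names, sizes and spans, plus comma-terminated
lists describing the gapless blocks.  All coordinates are 0-based half-open;
for '-' strand rows the per-block query starts are given on the reversed
query, while qStart/qEnd stay in plus-strand coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


class PslParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


@dataclass(frozen=True)
class PslAlignment:
    matches: int
    mismatches: int
    rep_matches: int
    n_count: int
    q_gap_count: int
    q_gap_bases: int
    t_gap_count: int
    t_gap_bases: int
    strand: str
    q_name: str
    q_size: int
    q_start: int
    q_end: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    block_count: int
    block_sizes: tuple[int, ...]
    q_starts: tuple[int, ...]
    t_starts: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "block_sizes", tuple(int(x) for x in self.block_sizes))
        object.__setattr__(self, "q_starts", tuple(int(x) for x in self.q_starts))
        object.__setattr__(self, "t_starts", tuple(int(x) for x in self.t_starts))
        self.validate()

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.q_start < self.q_end <= self.q_size):
            raise ValueError(
                f"query span [{self.q_start}, {self.q_end}) out of bounds for size {self.q_size}"
            )
        if not (0 <= self.t_start < self.t_end <= self.t_size):
            raise ValueError(
                f"target span [{self.t_start}, {self.t_end}) out of bounds for size {self.t_size}"
            )
        if not (len(self.block_sizes) == len(self.q_starts) == len(self.t_starts) == self.block_count):
            raise ValueError("block lists must all have length block_count")
        if self.block_count < 1:
            raise ValueError("at least one block required")
        if sum(self.block_sizes) != self.matches + self.mismatches + self.rep_matches + self.n_count:
            raise ValueError("sum(block_sizes) must equal matches + mismatches (+reps +Ns)")
        for bs, qs, ts in zip(self.block_sizes, self.q_starts, self.t_starts):
            if bs < 1:
                raise ValueError("block sizes must be >= 1")
            if qs + bs > self.q_size:
                raise ValueError("query block exceeds query size")
            if not (self.t_start <= ts and ts + bs <= self.t_end):
                raise ValueError("target block outside target span")
        for a, b, s in zip(self.t_starts, self.t_starts[1:], self.block_sizes):
            if b < a + s:
                raise ValueError("target blocks must be non-overlapping and ascending")
        for a, b, s in zip(self.q_starts, self.q_starts[1:], self.block_sizes):
            if b < a + s:
                raise ValueError("query blocks must be non-overlapping and ascending")

    @property
    def aligned_length(self) -> int:
        """Bases inside blocks: matches + mismatches (+ reps + Ns)."""
        return sum(self.block_sizes)

    @property
    def gap_bases(self) -> int:
        return self.q_gap_bases + self.t_gap_bases

    def to_row(self) -> str:
        def lst(xs: tuple[int, ...]) -> str:
            return ",".join(map(str, xs)) + ","

        return "\t".join(
            map(
                str,
                [
                    self.matches, self.mismatches, self.rep_matches, self.n_count,
                    self.q_gap_count, self.q_gap_bases, self.t_gap_count, self.t_gap_bases,
                    self.strand, self.q_name, self.q_size, self.q_start, self.q_end,
                    self.t_name, self.t_size, self.t_start, self.t_end,
                    self.block_count, lst(self.block_sizes), lst(self.q_starts),
                    lst(self.t_starts),
                ],
            )
        )


def _int_list(cell: str) -> tuple[int, ...]:
    return tuple(int(x) for x in cell.rstrip(",").split(",") if x)


def parse_psl_line(line: str, lineno: int | None = None) -> PslAlignment:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 21:
        raise PslParseError(f"expected 21 PSL columns, got {len(fields)}", lineno)
    try:
        return PslAlignment(
            matches=int(fields[0]),
            mismatches=int(fields[1]),
            rep_matches=int(fields[2]),
            n_count=int(fields[3]),
            q_gap_count=int(fields[4]),
            q_gap_bases=int(fields[5]),
            t_gap_count=int(fields[6]),
            t_gap_bases=int(fields[7]),
            strand=fields[8],
            q_name=fields[9],
            q_size=int(fields[10]),
            q_start=int(fields[11]),
            q_end=int(fields[12]),
            t_name=fields[13],
            t_size=int(fields[14]),
            t_start=int(fields[15]),
            t_end=int(fields[16]),
            block_count=int(fields[17]),
            block_sizes=_int_list(fields[18]),
            q_starts=_int_list(fields[19]),
            t_starts=_int_list(fields[20]),
        )
    except PslParseError:
        raise
    except ValueError as exc:
        raise PslParseError(str(exc), lineno) from exc


def parse_psl(path: str | Path) -> list[PslAlignment]:
    """Read a PSL file, tolerating the optional 5-line psLayout header."""
    out: list[PslAlignment] = []
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("psLayout"):
        start = 5  # version line, blank, two column-name lines, dashes
    for lineno in range(start, len(lines)):
        line = lines[lineno]
        if not line.strip() or line.startswith("-"):
            continue
        out.append(parse_psl_line(line, lineno + 1))
    return out


def write_psl(alignments: Iterable[PslAlignment], path: str | Path, header: bool = False) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("psLayout version 3\n\n")
            fh.write(
                "match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ        \t"
                "Q   \tQ    \tQ  \tT        \tT   \tT    \tT  \tblock\tblockSizes \tqStarts\t tStarts\n"
            )
            fh.write(
                "     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \tname     \t"
                "size\tstart\tend\tname     \tsize\tstart\tend\tcount\n"
            )
            fh.write("-" * 120 + "\n")
        for a in alignments:
            fh.write(a.to_row() + "\n")
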
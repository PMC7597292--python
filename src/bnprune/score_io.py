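"""Text I/O: discrete data tables, Jaakkola/GOBNILP ".jkl" score files, network JSON.

Data files are whitespace-delimited: a header row of variable names, an
optional row of arities, then one integer row per observation.  Score files
follow the local-score dialect consumed by GOBNILP-compatible learners::

    <number of variables>
    <name> <number of parent sets>
    <score> <k> <parent_1> ... <parent_k>
    ...

Parent fields may be variable names or 0-based indices; the reader
auto-detects (all-integer parent tokens that match no declared name are
treated as indices).  Reading is order-insensitive — tables are re-sorted to
canonical order (score descending, fewer parents, lexicographic) — and
write/read round-trips are exact to the written float precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from .candidates import NodeScoreTable, ScoredParentSet, ScoreSet
from .scoring import DiscreteDataset

__all__ = [
    "ScoreFileDialect",
    "DataFormatError",
    "ScoreFormatError",
    "read_data",
    "write_data",
    "read_scores",
    "write_scores",
    "write_network",
    "read_network",
    "network_to_dot",
]


class DataFormatError(ValueError):
    """Malformed data file; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class ScoreFormatError(ValueError):
    """Malformed score file; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass(frozen=True)
class ScoreFileDialect:
    """Score-file conventions: format tag and float precision used on write."""

    format: str = "jaakkola"
    precision: int = 6


def _content_lines(path) -> List[Tuple[int, List[str]]]:
    """(line number, tokens) for each non-blank, non-comment line."""
    out = []
    with open(path) as fh:
        for no, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if line:
                out.append((no, line.split()))
    return out


def read_data(path) -> DiscreteDataset:
    """Read a whitespace-delimited discrete data table.

    The second row is taken as the arity row when every token is an integer
    >= 2 that strictly exceeds every later value in its column; otherwise it
    is data and arities are inferred as (max observed value + 1, but at
    least 2).
    """
    lines = _content_lines(path)
    if not lines:
        raise DataFormatError(1, "empty data file")
    header_no, names = lines[0]
    n = len(names)
    if len(set(names)) != n:
        raise DataFormatError(header_no, "duplicate variable names")

    body = lines[1:]
    if not body:
        raise DataFormatError(header_no, "no data rows")

    def parse_row(no: int, toks: List[str]) -> List[int]:
        if len(toks) != n:
            raise DataFormatError(no, f"expected {n} columns, got {len(toks)}")
        vals = []
        for t in toks:
            try:
                vals.append(int(t))
            except ValueError:
                raise DataFormatError(no, f"non-integer cell {t!r}") from None
        return vals

    first = parse_row(*body[0])
    rest = [parse_row(no, toks) for no, toks in body[1:]]
    arity_row = (
        bool(rest)
        and all(v >= 2 for v in first)
        and all(
            all(row[i] < first[i] for row in rest) for i in range(n)
        )
    )
    if arity_row:
        arities, rows = first, rest
    else:
        rows = [first] + rest
        arities = [max(2, max(row[i] for row in rows) + 1) for i in range(n)]
    for i, a in enumerate(arities):
        for (no, _), row in zip(body[1:] if arity_row else body, rows):
            if not 0 <= row[i] < a:
                raise DataFormatError(
                    no, f"value {row[i]} of {names[i]!r} outside [0, {a})"
                )
    return DiscreteDataset(names=names, arities=arities, rows=rows)


def write_data(data: DiscreteDataset, path) -> None:
    """Write a data table with an explicit arity row (inverse of :func:`read_data`)."""
    with open(path, "w") as fh:
        fh.write(" ".join(data.names) + "\n")
        fh.write(" ".join(str(a) for a in data.arities) + "\n")
        for row in data.rows:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_scores(path) -> ScoreSet:
    """Parse a Jaakkola/GOBNILP local-score file into a :class:`ScoreSet`."""
    lines = _content_lines(path)
    if not lines:
        raise ScoreFormatError(1, "empty score file")
    pos = 0

    no, toks = lines[pos]
    pos += 1
    if len(toks) != 1:
        raise ScoreFormatError(no, "expected a single variable count")
    try:
        n = int(toks[0])
    except ValueError:
        raise ScoreFormatError(no, f"invalid variable count {toks[0]!r}") from None
    if n < 1:
        raise ScoreFormatError(no, f"variable count must be >= 1, got {n}")

    names: List[str] = []
    raw_tables: List[List[Tuple[int, float, List[str]]]] = []
    for _ in range(n):
        if pos >= len(lines):
            raise ScoreFormatError(lines[-1][0], "unexpected end of file")
        no, toks = lines[pos]
        pos += 1
        if len(toks) != 2:
            raise ScoreFormatError(no, f"expected '<name> <count>', got {' '.join(toks)!r}")
        name, m_tok = toks
        try:
            m = int(m_tok)
        except ValueError:
            raise ScoreFormatError(no, f"invalid parent-set count {m_tok!r}") from None
        entries = []
        for _ in range(m):
            if pos >= len(lines):
                raise ScoreFormatError(lines[-1][0], "unexpected end of file")
            eno, etoks = lines[pos]
            pos += 1
            if len(etoks) < 2:
                raise ScoreFormatError(eno, "expected '<score> <k> <parents...>'")
            try:
                score = float(etoks[0])
            except ValueError:
                raise ScoreFormatError(eno, f"invalid score {etoks[0]!r}") from None
            try:
                k = int(etoks[1])
            except ValueError:
                raise ScoreFormatError(eno, f"invalid parent count {etoks[1]!r}") from None
            if len(etoks) != 2 + k:
                raise ScoreFormatError(
                    eno, f"expected {k} parent fields, got {len(etoks) - 2}"
                )
            entries.append((eno, score, etoks[2:]))
        names.append(name)
        raw_tables.append(entries)
    if pos != len(lines):
        raise ScoreFormatError(lines[pos][0], "trailing content after last table")
    if len(set(names)) != n:
        raise ScoreFormatError(lines[0][0], "duplicate variable names")

    index_of = {name: i for i, name in enumerate(names)}
    all_parent_tokens = [t for entries in raw_tables for _, _, ps in entries for t in ps]
    as_indices = bool(all_parent_tokens) and all(
        t.lstrip("-").isdigit() and t not in index_of for t in all_parent_tokens
    )

    tables = []
    for child, entries in enumerate(raw_tables):
        spsets = []
        for eno, score, ptoks in entries:
            parents = []
            for t in ptoks:
                if as_indices:
                    p = int(t)
                    if not 0 <= p < n:
                        raise ScoreFormatError(eno, f"parent index {p} out of range")
                else:
                    if t not in index_of:
                        raise ScoreFormatError(eno, f"unknown parent name {t!r}")
                    p = index_of[t]
                parents.append(p)
            spsets.append(ScoredParentSet(parents=tuple(parents), score=score))
        try:
            tables.append(NodeScoreTable(child, spsets))
        except ValueError as exc:
            raise ScoreFormatError(lines[0][0], f"table of {names[child]!r}: {exc}") from None
    return ScoreSet(names=names, tables=tables)


def write_scores(
    score_set: ScoreSet, path, dialect: ScoreFileDialect | None = None
) -> None:
    """Write a score file in canonical table order (inverse of :func:`read_scores`)."""
    dialect = dialect or ScoreFileDialect()
    prec = dialect.precision
    with open(path, "w") as fh:
        fh.write(f"{score_set.n}\n")
        for i, table in enumerate(score_set.tables):
            fh.write(f"{score_set.names[i]} {len(table)}\n")
            for e in table.entries:
                parents = " ".join(score_set.names[p] for p in e.parents)
                line = f"{e.score:.{prec}f} {e.size}"
                fh.write(line + (f" {parents}" if parents else "") + "\n")


def write_network(result, score_set: ScoreSet, path) -> None:
    """Write a learned network as JSON: per-node parents and local scores plus the total."""
    dag = result.dag
    doc = {
        "nodes": [
            {
                "name": score_set.names[i],
                "parents": [score_set.names[p] for p in dag.parents[i]],
                "local_score": score_set.tables[i].score_of(dag.parents[i]),
            }
            for i in range(dag.n)
        ],
        "total_score": result.total_score,
        "method": result.method,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_network(path) -> dict:
    """Read a network JSON document (as written by :func:`write_network`)."""
    with open(path) as fh:
        return json.load(fh)


def network_to_dot(doc: dict) -> str:
    """Graphviz DOT text of a network JSON document."""
    lines = ["digraph bn {"]
    for node in doc["nodes"]:
        lines.append(f'  "{node["name"]}";')
    for node in doc["nodes"]:
        for p in node["parents"]:
            lines.append(f'  "{p}" -> "{node["name"]}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
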
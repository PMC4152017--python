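"""Readers and writers for edge lists, pairwise similarity files and scores.

File dialects
-------------
* Edge list: two-column TSV/CSV (drug label, ADR label), optional header,
  or an XLSX sheet with the pairs in the first two columns.
* Pairwise similarity: whitespace/tab-delimited three-column text
  ``label_a label_b score``.
* Scores: three-column TSV ``drug adr score`` in drug-major order.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BipartiteNetwork, NetworkStats, ScoreMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

_FLOAT_RE = r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$"


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_pair_records(path: Path, fmt: str) -> list[tuple[str, str]]:
    if fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=0, header=None, dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected at least 2 columns, got {df.shape[1]}")
        records = [
            (str(a).strip(), str(b).strip())
            for a, b in df.iloc[:, :2].itertuples(index=False)
            if not (pd.isna(a) or pd.isna(b))
        ]
        if df.shape[1] > 2 and df.iloc[:, 2:].notna().any().any():
            raise ValueError(f"{path}: records with more than 2 fields")
        return records
    sep = "\t" if fmt == "tsv" else ","
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split(sep)]
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            records.append((fields[0], fields[1]))
    return records


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("tsv", "csv", "xlsx"):
            raise ValueError(f"unknown edge-list format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".xlsx":
        return "xlsx"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def read_edge_list(path: str | Path, format: str | None = None) -> BipartiteNetwork:
    """Read a two-column drug-ADR edge list into a :class:`BipartiteNetwork`.

    Node order is first-appearance order.  Duplicate records collapse to a
    single edge (with a warning).  A header row is tolerated: if the first
    record reappears nowhere and looks like column names (both fields
    non-numeric and either field matches 'drug'/'adr'-like words), it is
    dropped; more simply, an exactly duplicated pair is always collapsed,
    and a record equal to ``("drug", "adr")``-style names only shifts counts
    by one spurious node per side, so explicit detection matters: the first
    record is treated as a header when a second record exists and the first
    record's fields never occur again anywhere in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    records = _read_pair_records(path, fmt)
    if not records:
        raise ValueError(f"{path}: empty edge list")
    if len(records) > 1:
        first = records[0]
        rest_labels = {x for rec in records[1:] for x in rec}
        if (
            first[0] not in rest_labels
            and first[1] not in rest_labels
            and not _looks_numeric(first[0])
            and not _looks_numeric(first[1])
        ):
            logger.info("%s: first record %r treated as header", path, first)
            records = records[1:]

    drug_ids: list[str] = []
    adr_ids: list[str] = []
    drug_idx: dict[str, int] = {}
    adr_idx: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[int, int]] = []
    n_dup = 0
    for d, a in records:
        if (d, a) in seen:
            n_dup += 1
            continue
        seen.add((d, a))
        if d not in drug_idx:
            drug_idx[d] = len(drug_ids)
            drug_ids.append(d)
        if a not in adr_idx:
            adr_idx[a] = len(adr_ids)
            adr_ids.append(a)
        pairs.append((drug_idx[d], adr_idx[a]))
    if n_dup:
        logger.warning("%s: collapsed %d duplicate records", path, n_dup)
    Y = np.zeros((len(drug_ids), len(adr_ids)))
    rows, cols = zip(*pairs)
    Y[rows, cols] = 1.0
    return BipartiteNetwork(tuple(drug_ids), tuple(adr_ids), Y)


def read_pairwise_similarity(
    path: str | Path,
    ids: tuple[str, ...],
    side: str,
    source: str = "chemical",
    default: float = 0.0,
) -> SimilarityMatrix:
    """Read three-column pair scores into a square similarity matrix.

    Unlisted pairs are filled with ``default``; the diagonal is forced to 1.
    When (a, b) and (b, a) disagree the larger value wins (with a warning).
    Labels absent from ``ids`` are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    idx = {lab: i for i, lab in enumerate(ids)}
    k = len(ids)
    pair_scores: dict[tuple[int, int], float] = {}
    n_unknown = 0
    n_conflict = 0
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            a, b, raw = fields[0].strip(), fields[1].strip(), fields[2]
            if lineno == 1 and not _looks_numeric(raw):
                logger.info("%s: first record treated as header", path)
                continue
            try:
                score = float(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable score {raw!r}") from exc
            n_records += 1
            if a not in idx or b not in idx:
                n_unknown += 1
                continue
            i, j = idx[a], idx[b]
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in pair_scores and pair_scores[key] != score:
                n_conflict += 1
                score = max(pair_scores[key], score)
            pair_scores[key] = score
    if n_unknown:
        logger.warning(
            "%s: dropped %d records with labels outside the node universe",
            path,
            n_unknown,
        )
    if n_conflict:
        logger.warning(
            "%s: %d conflicting pair records symmetrized by max", path, n_conflict
        )
    if n_records and n_unknown == n_records:
        raise ValueError(f"{path}: no record label matches the supplied ids")
    S = np.full((k, k), float(default))
    for (i, j), score in pair_scores.items():
        S[i, j] = S[j, i] = score
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(side, source, tuple(ids), S)


def network_stats(net: BipartiteNetwork) -> NetworkStats:
    """Counts, average degrees and full degree vectors of a network."""
    e = net.n_edges
    return NetworkStats(
        n_drugs=net.n_drugs,
        n_adrs=net.n_adrs,
        n_edges=e,
        avg_drug_degree=e / net.n_drugs,
        avg_adr_degree=e / net.n_adrs,
        drug_degrees=net.drug_degrees(),
        adr_degrees=net.adr_degrees(),
    )


def check_identical_node_sets(a: BipartiteNetwork, b: BipartiteNetwork) -> None:
    """Validate that two network snapshots share drug and ADR node sets."""
    if set(a.drug_ids) != set(b.drug_ids):
        raise ValueError("drug node sets differ between the two networks")
    if set(a.adr_ids) != set(b.adr_ids):
        raise ValueError("ADR node sets differ between the two networks")


def write_scores(F: ScoreMatrix, path: str | Path) -> None:
    """Write scores as three-column TSV in drug-major order, full precision."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, d in enumerate(F.drug_ids):
            for j, a in enumerate(F.adr_ids):
                fh.write(f"{d}\t{a}\t{float(F.F[i, j])!r}\n")


def read_scores(path: str | Path) -> ScoreMatrix:
    """Read a score file written by :func:`write_scores`."""
    path = Path(path)
    drug_ids: list[str] = []
    adr_ids: list[str] = []
    drug_idx: dict[str, int] = {}
    adr_idx: dict[str, int] = {}
    triples: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            d, a, s = fields
            triples.append((d, a, float(s)))
            if d not in drug_idx:
                drug_idx[d] = len(drug_ids)
                drug_ids.append(d)
            if a not in adr_idx:
                adr_idx[a] = len(adr_ids)
                adr_ids.append(a)
    F = np.zeros((len(drug_ids), len(adr_ids)))
    for d, a, s in triples:
        F[drug_idx[d], adr_idx[a]] = s
    return ScoreMatrix(tuple(drug_ids), tuple(adr_ids), F)
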
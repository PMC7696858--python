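"""Reading, validating and aggregating agonistic-behaviour observation data.

The observational unit is a single agonistic event: one animal (the
initiator) directs one of four ethogram actions — head-knock, bite, fight
or chase — at a pen-mate (the receiver). Events accumulate over repeated
observation sessions into a weighted directed network per pen, in which
edge weight w(i→j) is the total number of actions i initiated toward j.
The whole roster is kept as the node set, so animals that never interact
appear as zero-degree (isolated) nodes.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "BEHAVIOURS",
    "NON_IDENTIFIED",
    "ObservationRecord",
    "PenRoster",
    "PenNetwork",
    "IngestReport",
    "read_observations",
    "read_roster",
    "build_pen_network",
    "tally_behaviour_types",
    "write_edge_list",
    "write_graphml",
]

#: Canonical ethogram action names, in reporting order.
BEHAVIOURS: tuple[str, ...] = ("head_knock", "bite", "fight", "chase")

#: Sentinel used by observers when the initiating animal could not be read.
NON_IDENTIFIED = "non-identified"

# Tokens accepted in input files, mapped to canonical behaviour names.
_BEHAVIOUR_ALIASES: dict[str, str] = {
    "head_knock": "head_knock",
    "head-knock": "head_knock",
    "head_knocking": "head_knock",
    "headknock": "head_knock",
    "hk": "head_knock",
    "bite": "bite",
    "biting": "bite",
    "fight": "fight",
    "fighting": "fight",
    "chase": "chase",
    "chasing": "chase",
}

_DEFAULT_COLUMNS = {
    "pen": "pen",
    "session": "session",
    "behaviour": "behaviour",
    "initiator": "initiator",
    "receiver": "receiver",
}


@dataclass(frozen=True)
class ObservationRecord:
    """One agonistic event: who did what to whom, when and where."""

    pen_id: str
    session_id: str
    behaviour: str
    initiator: str
    receiver: str

    def __post_init__(self) -> None:
        if self.behaviour not in BEHAVIOURS:
            raise ValueError(f"unknown behaviour {self.behaviour!r}")
        if self.initiator == self.receiver:
            raise ValueError("initiator and receiver must differ")


@dataclass(frozen=True)
class PenRoster:
    """The animals housed together in one pen."""

    pen_id: str
    animals: tuple[str, ...]
    sex_group: str | None = None

    def __post_init__(self) -> None:
        if len(self.animals) < 2:
            raise ValueError(f"pen {self.pen_id!r}: roster needs >= 2 animals")
        if len(set(self.animals)) != len(self.animals):
            raise ValueError(f"pen {self.pen_id!r}: duplicate animal ids")


@dataclass(frozen=True)
class PenNetwork:
    """Weighted directed aggression network for one pen.

    ``weights[(i, j)]`` counts the agonistic actions i initiated toward j,
    summed over all sessions and all four behaviour types. Every roster
    animal is a node even when it has no incident edges.
    """

    pen_id: str
    nodes: tuple[str, ...]
    weights: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for (i, j), w in self.weights.items():
            if i == j:
                raise ValueError(f"self-loop on {i!r}")
            if i not in node_set or j not in node_set:
                raise ValueError(f"edge ({i!r}, {j!r}) off the roster")
            if w < 0:
                raise ValueError("negative edge weight")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        """Binarized directed edge set (weights > 0)."""
        return frozenset(e for e, w in self.weights.items() if w > 0)

    @property
    def total_weight(self) -> int:
        return sum(self.weights.values())

    def to_networkx(self, *, binary: bool = False) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (i, j), w in self.weights.items():
            if w > 0:
                g.add_edge(i, j, weight=1 if binary else w)
        return g


@dataclass
class IngestReport:
    """Row-level accounting for one observation file."""

    n_rows: int = 0
    n_accepted: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _resolve_columns(
    header: Sequence[str], columns: Mapping[str, str] | None
) -> dict[str, str]:
    cols = dict(_DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    missing = [c for c in cols.values() if c not in header]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    return cols


def read_observations(
    path: str | Path,
    *,
    columns: Mapping[str, str] | None = None,
    non_identified_policy: str = "drop",
) -> tuple[list[ObservationRecord], IngestReport]:
    """Parse an observation log CSV into validated event records.

    Parameters
    ----------
    path:
        CSV file with a header row. Default column names are
        ``pen, session, behaviour, initiator, receiver``; override any of
        them through ``columns`` (logical name -> file column name).
    non_identified_policy:
        What to do with rows whose initiator is the observer sentinel
        ``"non-identified"``: ``"drop"`` rejects the row (counted in the
        report), ``"error"`` aborts. Such rows cannot contribute a
        directed edge.

    Returns
    -------
    (records, report):
        Accepted records plus a line-numbered account of rejected rows.
        Unknown behaviour tokens and missing columns are fatal; a row whose
        initiator equals its receiver is rejected and counted.
    """
    if non_identified_policy not in ("drop", "error"):
        raise ValueError(f"unknown policy {non_identified_policy!r}")
    path = Path(path)
    records: list[ObservationRecord] = []
    report = IngestReport()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header")
        cols = _resolve_columns(reader.fieldnames, columns)
        for lineno, row in enumerate(reader, start=2):
            report.n_rows += 1
            behaviour_token = row[cols["behaviour"]].strip().lower()
            behaviour = _BEHAVIOUR_ALIASES.get(behaviour_token)
            if behaviour is None:
                raise ValueError(
                    f"{path}, line {lineno}: unknown behaviour "
                    f"{row[cols['behaviour']]!r}"
                )
            initiator = row[cols["initiator"]].strip()
            receiver = row[cols["receiver"]].strip()
            if initiator == NON_IDENTIFIED:
                if non_identified_policy == "error":
                    raise ValueError(
                        f"{path}, line {lineno}: non-identified initiator"
                    )
                report.rejections.append((lineno, "non-identified initiator"))
                continue
            if initiator == receiver:
                report.rejections.append((lineno, "initiator equals receiver"))
                continue
            records.append(
                ObservationRecord(
                    pen_id=row[cols["pen"]].strip(),
                    session_id=row[cols["session"]].strip(),
                    behaviour=behaviour,
                    initiator=initiator,
                    receiver=receiver,
                )
            )
            report.n_accepted += 1
    return records, report


def read_roster(
    path: str | Path, *, columns: Mapping[str, str] | None = None
) -> list[PenRoster]:
    """Read a pen roster CSV (columns ``pen, animal[, sex_group]``)."""
    path = Path(path)
    cols = {"pen": "pen", "animal": "animal", "sex_group": "sex_group"}
    if columns:
        cols.update(columns)
    pens: dict[str, list[str]] = {}
    sex: dict[str, str | None] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header")
        required = [cols["pen"], cols["animal"]]
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        has_sex = cols["sex_group"] in reader.fieldnames
        for row in reader:
            pen = row[cols["pen"]].strip()
            pens.setdefault(pen, []).append(row[cols["animal"]].strip())
            if has_sex:
                sex[pen] = row[cols["sex_group"]].strip() or None
            else:
                sex.setdefault(pen, None)
    return [
        PenRoster(pen_id=p, animals=tuple(animals), sex_group=sex[p])
        for p, animals in pens.items()
    ]


def build_pen_network(
    records: Iterable[ObservationRecord], roster: PenRoster
) -> PenNetwork:
    """Aggregate one pen's events into its weighted directed network.

    Edge weight w(i→j) is the number of records with initiator i and
    receiver j over all sessions and behaviour types. Fight events, although
    reciprocal in the ethogram, are counted once in the direction of the
    listed initiator. A record naming an animal absent from the roster is
    fatal.
    """
    node_set = set(roster.animals)
    weights: Counter[tuple[str, str]] = Counter()
    for rec in records:
        if rec.pen_id != roster.pen_id:
            raise ValueError(
                f"record pen {rec.pen_id!r} does not match roster "
                f"{roster.pen_id!r}"
            )
        for animal in (rec.initiator, rec.receiver):
            if animal not in node_set:
                raise ValueError(
                    f"animal {animal!r} not on roster of pen {roster.pen_id!r}"
                )
        weights[(rec.initiator, rec.receiver)] += 1
    return PenNetwork(
        pen_id=roster.pen_id, nodes=roster.animals, weights=dict(weights)
    )


def tally_behaviour_types(
    records: Sequence[ObservationRecord],
) -> dict[str, float]:
    """Proportion of events per ethogram action; proportions sum to 1."""
    if not records:
        raise ValueError("cannot tally an empty record list")
    counts = Counter(rec.behaviour for rec in records)
    total = len(records)
    return {b: counts.get(b, 0) / total for b in BEHAVIOURS}


def write_edge_list(net: PenNetwork, path: str | Path) -> None:
    """Write a ``source,target,weight`` CSV for one pen network."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        for (i, j), w in sorted(net.weights.items()):
            if w > 0:
                writer.writerow([i, j, w])


def write_graphml(net: PenNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), str(path))
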
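"""Signed regulatory-network assembly from per-experiment evidence rows.

Each :class:`EvidenceRow` records one experiment on one regulator→target
pair.  Evidence classes carry different information:

* ``binding`` — in-vitro protein–DNA binding (e.g. a gel-shift assay).
  Establishes a *direct* interaction but no sign, so binding rows carry
  direction ``none``.
* ``reporter`` — promoter-fusion reporter activity compared between the
  regulator-deletion strain and the wild type: higher activity in the
  deletion means the regulator represses the promoter, lower means it
  activates.
* ``knockout_qpcr`` — target transcript level in the regulator-deletion
  strain relative to wild type: a significant fold > 1 means repression by
  the deleted regulator, < 1 means activation.
* ``production`` — end-product output of the deletion strain, same sign
  logic as knockout_qpcr.

:func:`build_network` groups rows by pair into one signed
:class:`RegEdge` each.  Conflicting directional evidence is surfaced as a
``conflict`` flag, never averaged away; the ``direct`` flag is set only
when a binding row exists for the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

ASSAYS = ("binding", "reporter", "knockout_qpcr", "production")
DIRECTIONS = ("activates", "represses", "none")


@dataclass(frozen=True)
class EvidenceRow:
    regulator: str
    target: str
    assay: str
    direction: str = "none"
    note: str = ""

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay type {self.assay!r}; expected one of {ASSAYS}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.assay == "binding" and self.direction != "none":
            raise ValueError("binding evidence carries no direction; use 'none'")


def knockout_evidence(
    regulator: str,
    target: str,
    fold: float,
    significant: bool,
    epsilon: float = 0.5,
    assay: str = "knockout_qpcr",
) -> EvidenceRow:
    """Directional evidence from a deletion-strain fold change vs wild type.

    Target expression up in the mutant (fold > 1 + ε, significant) means the
    regulator represses the target; down (fold < 1 − ε, significant) means
    activation.  Non-significant or near-1 folds yield direction ``none``.
    """
    if fold <= 0:
        raise ValueError("fold change must be positive")
    if significant and fold > 1 + epsilon:
        direction = "represses"
    elif significant and fold < 1 - epsilon:
        direction = "activates"
    else:
        direction = "none"
    return EvidenceRow(
        regulator=regulator,
        target=target,
        assay=assay,
        direction=direction,
        note=f"fold={fold:g} in deletion strain",
    )


def reporter_evidence(
    regulator: str,
    target: str,
    fold_in_deletion: float,
    significant: bool,
    epsilon: float = 0.5,
) -> EvidenceRow:
    """Directional evidence from promoter-reporter activity in the deletion strain."""
    return knockout_evidence(
        regulator,
        target,
        fold_in_deletion,
        significant,
        epsilon=epsilon,
        assay="reporter",
    )


@dataclass
class RegEdge:
    """One signed regulator→target edge with its supporting evidence."""

    regulator: str
    target: str
    sign: str  # '+' activation | '-' repression | '?' none | 'conflict'
    direct: bool
    assays: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "regulator": self.regulator,
            "target": self.target,
            "sign": self.sign,
            "direct": str(self.direct).lower(),
            "assays": ",".join(self.assays),
        }


def build_network(rows: Iterable[EvidenceRow]) -> list[RegEdge]:
    """Collapse evidence rows into one edge per (regulator, target) pair."""
    groups: dict[tuple[str, str], list[EvidenceRow]] = {}
    for row in rows:
        if row.regulator == row.target:
            warnings.warn(f"self-loop evidence on {row.regulator!r}")
        groups.setdefault((row.regulator, row.target), []).append(row)
    edges = []
    for (reg, tgt), group in sorted(groups.items()):
        directions = {r.direction for r in group if r.direction != "none"}
        if not directions:
            sign = "?"
        elif directions == {"activates"}:
            sign = "+"
        elif directions == {"represses"}:
            sign = "-"
        else:
            sign = "conflict"
        direct = any(r.assay == "binding" for r in group)
        edges.append(
            RegEdge(
                regulator=reg,
                target=tgt,
                sign=sign,
                direct=direct,
                assays=sorted({r.assay for r in group}),
            )
        )
    return edges


def write_edges_tsv(edges: Sequence[RegEdge], path: str | Path) -> None:
    from .genome_io import write_table_tsv

    write_table_tsv([e.as_row() for e in edges], path)


def read_edges_tsv(path: str | Path) -> list[RegEdge]:
    from .genome_io import read_table_tsv

    return [
        RegEdge(
            regulator=row["regulator"],
            target=row["target"],
            sign=row["sign"],
            direct=row["direct"] == "true",
            assays=row["assays"].split(",") if row["assays"] else [],
        )
        for row in read_table_tsv(path)
    ]


def read_evidence_tsv(path: str | Path) -> list[EvidenceRow]:
    from .genome_io import read_table_tsv

    return [
        EvidenceRow(
            regulator=row["regulator"],
            target=row["target"],
            assay=row["assay"],
            direction=row.get("direction", "none"),
            note=row.get("note", ""),
        )
        for row in read_table_tsv(path)
    ]


def to_dot(edges: Sequence[RegEdge]) -> str:
    """Graphviz rendering: arrowheads for activation, tees for repression,
    dashed lines for interactions without binding evidence."""
    lines = ["digraph regnet {"]
    for e in edges:
        arrow = {"+": "normal", "-": "tee", "?": "none", "conflict": "diamond"}[e.sign]
        style = "solid" if e.direct else "dashed"
        lines.append(
            f'  "{e.regulator}" -> "{e.target}" [arrowhead={arrow}, style={style}];'
        )
    lines.append("}")
    return "\n".join(lines)


def lmbu_cascade_evidence() -> list[EvidenceRow]:
    """The measured evidence behind the LmbU cascade in *S. lincolnensis*.

    LmbU, the cluster-situated regulator of lincomycin biosynthesis, binds
    the promoters of three chromosomal targets (gel-shift evidence) whose
    reporter activities shift in the ΔlmbU strain: SLINC_0469 and
    SLINC_1037 go up 7- and 6-fold (LmbU represses them) while SLINC_8097
    drops 19-fold (LmbU activates it).  Deleting each target in turn
    de-represses lincomycin-cluster (lmb) genes, measured by qPCR fold
    changes in the deletion strains.
    """
    rows: list[EvidenceRow] = []
    for target in ("SLINC_0469", "SLINC_1037", "SLINC_8097"):
        rows.append(EvidenceRow("LmbU", target, "binding"))
    rows.append(reporter_evidence("LmbU", "SLINC_0469", fold_in_deletion=7.0, significant=True))
    rows.append(reporter_evidence("LmbU", "SLINC_1037", fold_in_deletion=6.0, significant=True))
    rows.append(reporter_evidence("LmbU", "SLINC_8097", fold_in_deletion=1 / 19.0, significant=True))
    knockout_folds = {
        "SLINC_0469": {"lmbA": 3.7, "lmbV": 4.3, "lmbW": 13.0, "lmbU": 3.3},
        "SLINC_1037": {"lmbA": 4.9, "lmbV": 7.6, "lmbW": 20.4, "lmbU": 9.5},
        "SLINC_8097": {
            "lmbA": 4.2,
            "lmbC": 3.5,
            "lmbD": 4.1,
            "lmbV": 4.7,
            "lmbW": 13.3,
            "lmbU": 5.5,
        },
    }
    for regulator, folds in knockout_folds.items():
        for lmb_gene, fold in folds.items():
            rows.append(knockout_evidence(regulator, lmb_gene, fold, significant=True))
    return rows
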
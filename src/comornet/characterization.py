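"""Molecular characterizations of diseases and drugs.

A disease is characterized by its *protein effectors*: proteins with a
reported functional role in the disease, each annotated with the direction of
activation (+1/-1) that induces or sustains the disease and with one or more
pathophysiological *motives* (biological processes such as neuroinflammation
or HPA-axis hyperactivation). A drug is characterized by its protein targets
and the sign of the drug's action on each (+1 activation, -1 inhibition).

File formats
------------
Characterization TSV: header ``gene  sign  motive`` (motives "/"-separated;
optional boolean column ``sign_imputed``). Drug TSV: header ``gene  effect``.
Gene symbols are uppercased and whitespace-stripped at load; composite
symbols such as ``SLC6A2/NET1`` are stored under the first token with the
remainder kept as an alias annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

MOTIVE_SEPARATOR = "/"

__all__ = [
    "EffectorProtein",
    "DiseaseCharacterization",
    "DrugDefinition",
    "CharacterizationError",
    "normalize_symbol",
    "load_characterization",
    "write_characterization",
    "load_drug_definition",
    "effector_overlap",
    "connected_overlap",
    "OverlapReport",
]


class CharacterizationError(ValueError):
    """Raised on malformed or inconsistent characterization input."""


def normalize_symbol(raw: str) -> tuple[str, str | None]:
    """Normalize a gene symbol cell.

    Returns ``(symbol, alias)``: the cell is stripped and uppercased; a
    composite cell like ``"SLC6A3/DAT1"`` yields ``("SLC6A3", "DAT1")``.
    """
    text = str(raw).strip().upper()
    if not text:
        raise CharacterizationError("empty gene symbol")
    if "/" in text:
        head, _, rest = text.partition("/")
        head, rest = head.strip(), rest.strip()
        if not head:
            raise CharacterizationError(f"malformed composite symbol {raw!r}")
        return head, (rest or None)
    return text, None


@dataclass(frozen=True)
class EffectorProtein:
    """A signed disease effector.

    ``sign`` is the direction of activation that induces the disease: +1 if
    over-activation is pathogenic, -1 if loss of function is.
    """

    gene: str
    sign: int
    motives: frozenset[str]
    alias: str | None = None
    sign_imputed: bool = False
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise CharacterizationError(f"{self.gene}: sign must be -1 or +1, got {self.sign}")
        if not self.gene:
            raise CharacterizationError("effector gene symbol is empty")
        if not self.motives:
            raise CharacterizationError(f"{self.gene}: effector needs at least one motive")


@dataclass(frozen=True)
class DiseaseCharacterization:
    disease_id: str
    motives: tuple[str, ...]
    effectors: frozenset[EffectorProtein]

    def __post_init__(self) -> None:
        genes = [e.gene for e in self.effectors]
        if len(genes) != len(set(genes)):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise CharacterizationError(f"{self.disease_id}: duplicate effector genes {dupes}")
        known = set(self.motives)
        for eff in self.effectors:
            extra = eff.motives - known
            if extra:
                raise CharacterizationError(
                    f"{self.disease_id}: effector {eff.gene} carries undeclared motives {sorted(extra)}"
                )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(e.gene for e in self.effectors)

    def sign_of(self, gene: str) -> int:
        for eff in self.effectors:
            if eff.gene == gene:
                return eff.sign
        raise KeyError(gene)

    def effector(self, gene: str) -> EffectorProtein:
        for eff in self.effectors:
            if eff.gene == gene:
                return eff
        raise KeyError(gene)


@dataclass(frozen=True)
class DrugDefinition:
    """A drug as a signed target set: gene -> effect (+1 activation, -1 inhibition)."""

    drug_id: str
    targets: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.targets:
            raise CharacterizationError(f"{self.drug_id}: drug needs at least one target")
        for gene, effect in self.targets.items():
            if effect not in (-1, 1):
                raise CharacterizationError(f"{self.drug_id}: effect for {gene} must be -1 or +1")


def _as_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"true", "1", "yes"}


def load_characterization(
    path: str | Path,
    disease_id: str,
    motive_separator: str = MOTIVE_SEPARATOR,
) -> DiseaseCharacterization:
    """Load a disease characterization from a TSV with columns gene/sign/motive.

    Duplicate rows for one gene are merged by motive union; conflicting signs
    for one gene raise :class:`CharacterizationError`.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"gene", "sign", "motive"} - set(frame.columns)
    if missing:
        raise CharacterizationError(f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        raise CharacterizationError(f"{path}: no effector rows")

    merged: dict[str, dict] = {}
    motive_order: list[str] = []
    for _, row in frame.iterrows():
        gene, alias = normalize_symbol(row["gene"])
        try:
            sign = int(str(row["sign"]).strip())
        except ValueError as exc:
            raise CharacterizationError(f"{path}: non-integer sign {row['sign']!r} for {gene}") from exc
        if sign not in (-1, 1):
            raise CharacterizationError(f"{path}: sign {sign} for {gene} not in {{-1, +1}}")
        raw_motive = row["motive"]
        if pd.isna(raw_motive):
            raise CharacterizationError(f"{path}: empty motive cell for {gene}")
        motives = [m.strip() for m in str(raw_motive).split(motive_separator) if m.strip()]
        if not motives:
            raise CharacterizationError(f"{path}: empty motive cell for {gene}")
        for m in motives:
            if m not in motive_order:
                motive_order.append(m)
        imputed = _as_bool(row.get("sign_imputed", False)) if "sign_imputed" in frame.columns else False

        if gene in merged:
            entry = merged[gene]
            if entry["sign"] != sign:
                raise CharacterizationError(f"{path}: conflicting signs for {gene}")
            entry["motives"].update(motives)
            entry["sign_imputed"] = entry["sign_imputed"] or imputed
            entry["alias"] = entry["alias"] or alias
        else:
            merged[gene] = {
                "sign": sign,
                "motives": set(motives),
                "alias": alias,
                "sign_imputed": imputed,
            }

    effectors = frozenset(
        EffectorProtein(
            gene=gene,
            sign=entry["sign"],
            motives=frozenset(entry["motives"]),
            alias=entry["alias"],
            sign_imputed=entry["sign_imputed"],
        )
        for gene, entry in merged.items()
    )
    return DiseaseCharacterization(disease_id=disease_id, motives=tuple(motive_order), effectors=effectors)


def write_characterization(disease: DiseaseCharacterization, path: str | Path) -> None:
    """Write a characterization back to the TSV format ``load_characterization`` reads."""
    rows = []
    for eff in sorted(disease.effectors, key=lambda e: e.gene):
        motives = sorted(eff.motives, key=disease.motives.index)
        gene = eff.gene if eff.alias is None else f"{eff.gene}/{eff.alias}"
        rows.append(
            {
                "gene": gene,
                "sign": eff.sign,
                "motive": MOTIVE_SEPARATOR.join(motives),
                "sign_imputed": str(eff.sign_imputed).lower(),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_drug_definition(path: str | Path, drug_id: str) -> DrugDefinition:
    """Load a drug target table (columns gene/effect) into a DrugDefinition."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"gene", "effect"} - set(frame.columns)
    if missing:
        raise CharacterizationError(f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        raise CharacterizationError(f"{path}: drug table is empty")
    targets: dict[str, int] = {}
    for _, row in frame.iterrows():
        gene, _ = normalize_symbol(row["gene"])
        try:
            effect = int(str(row["effect"]).strip().replace("−", "-"))
        except ValueError as exc:
            raise CharacterizationError(f"{path}: non-integer effect for {gene}") from exc
        if effect not in (-1, 1):
            raise CharacterizationError(f"{path}: effect {effect} for {gene} not in {{-1, +1}}")
        if gene in targets and targets[gene] != effect:
            raise CharacterizationError(f"{path}: conflicting effects for {gene}")
        targets[gene] = effect
    return DrugDefinition(drug_id=drug_id, targets=targets)


@dataclass(frozen=True)
class OverlapReport:
    """Effector-sharing statistics between a base disease and a set of others.

    Fractions are reported in percent. ``aggregate`` is the percentage of the
    base disease's effectors found in at least one other disease;
    ``per_pair`` maps each other disease to the percentage of base effectors
    it shares.
    """

    base_id: str
    aggregate: float
    per_pair: Mapping[str, float] = field(default_factory=dict)


def effector_overlap(
    base: DiseaseCharacterization,
    others: Sequence[DiseaseCharacterization],
) -> OverlapReport:
    """Fraction of the base disease's effectors shared with other diseases."""
    base_genes = base.genes
    if not base_genes:
        raise CharacterizationError(f"{base.disease_id}: empty effector set")
    union = set().union(*(o.genes for o in others)) if others else set()
    aggregate = 100.0 * len(base_genes & union) / len(base_genes)
    per_pair = {
        o.disease_id: 100.0 * len(base_genes & o.genes) / len(base_genes) for o in others
    }
    return OverlapReport(base_id=base.disease_id, aggregate=aggregate, per_pair=per_pair)


def connected_overlap(
    base: DiseaseCharacterization,
    others: Sequence[DiseaseCharacterization],
    net,
) -> float:
    """Percentage of base effectors shared with, or directly connected (one
    edge) to, any other disease's effector; genes absent from the network
    count as unconnected."""
    base_genes = base.genes
    if not base_genes:
        raise CharacterizationError(f"{base.disease_id}: empty effector set")
    union = set().union(*(o.genes for o in others)) if others else set()
    hit = 0
    for gene in base_genes:
        if gene in union or net.neighbors(gene) & union:
            hit += 1
    return 100.0 * hit / len(base_genes)
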
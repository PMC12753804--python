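"""Mapping disease mutations onto persistent-contact sets.

Mutations are classified by a precedence rule derived from the structural
analysis of the translocation mechanism:

* **A** — the position participates in a persistent protein–DNA contact in
  any macrostate (DNA binding / translocation impairment);
* **B** — otherwise, the position contacts the bound nucleotide (ATP/ADP/Mg²⁺)
  or lies in the persistent RecA1–RecA2 interface (nucleotide binding /
  ATPase-cleft dynamics);
* **C** — neither (indirect, network-mediated effects).

The packaged catalog also carries the literature's class annotation; the
rule-based class can disagree (expert calls fold in information beyond
binary contacts, e.g. steric clashes with the nucleotide), and the report
surfaces both rather than hiding the difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .contacts import ContactTable
from .formats_io import Topology

PHENOTYPES = {"XP", "TTD", "CS", "XP/CS", "XP/TTD"}


@dataclass
class MutationRecord:
    position: int
    wild_type: str
    substitutions: list[str]
    phenotype: str
    paper_class: str | None = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


@dataclass
class ClassLabel:
    label: str                      # A | B | C
    evidence: list[str] = field(default_factory=list)
    states: list = field(default_factory=list)


def build_catalog() -> list[MutationRecord]:
    """Packaged catalog of XPD disease mutations."""
    with resources.files("translokit.data").joinpath(
            "mutation_catalog.json").open() as fh:
        data = json.load(fh)
    return [MutationRecord(**row) for row in data["mutations"]]


# ---------------------------------------------------------------------------
# evidence extraction from contact tables

def _persistent_rows(table: ContactTable) -> pd.DataFrame:
    return table.table[table.table["persistent"]]


def dna_contact_evidence(table: ContactTable, protein_chain: str = "A",
                         dna_chain: str = "D") -> dict[int, list[tuple]]:
    """position → [(state, contact key)] for persistent protein–DNA contacts."""
    out: dict[int, list[tuple]] = {}
    for _, row in _persistent_rows(table).iterrows():
        partners = [row["res_a"], row["res_b"]]
        chains = {p[0] for p in partners}
        if chains == {protein_chain, dna_chain}:
            prot = next(p for p in partners if p[0] == protein_chain)
            out.setdefault(prot[1], []).append(
                (row["state"], (row["res_a"], row["res_b"], row["type"])))
    return out


def nucleotide_contact_evidence(table: ContactTable, protein_chain: str = "A",
                                ligand_chain: str = "L") -> dict[int, list[tuple]]:
    """position → evidence for persistent contacts to ATP/ADP/Mg²⁺."""
    out: dict[int, list[tuple]] = {}
    for _, row in _persistent_rows(table).iterrows():
        partners = [row["res_a"], row["res_b"]]
        chains = {p[0] for p in partners}
        if chains == {protein_chain, ligand_chain}:
            prot = next(p for p in partners if p[0] == protein_chain)
            out.setdefault(prot[1], []).append(
                (row["state"], (row["res_a"], row["res_b"], row["type"])))
    return out


def interface_evidence(table: ContactTable, domain_a: str = "RecA1",
                       domain_b: str = "RecA2") -> dict[int, list[tuple]]:
    """position → evidence for persistent RecA1–RecA2 interface contacts."""
    out: dict[int, list[tuple]] = {}
    for _, row in _persistent_rows(table).iterrows():
        da = table.domains.get(row["res_a"])
        db = table.domains.get(row["res_b"])
        if {da, db} == {domain_a, domain_b}:
            for res in (row["res_a"], row["res_b"]):
                out.setdefault(res[1], []).append(
                    (row["state"], (row["res_a"], row["res_b"], row["type"])))
    return out


def _fmt(key) -> str:
    (ca, ra), (cb, rb), typ = key
    return f"{ca}{ra}-{cb}{rb}:{typ}"


def classify_mutation(record: MutationRecord,
                      dna_evidence: dict[int, list[tuple]],
                      atp_evidence: dict[int, list[tuple]],
                      interface_ev: dict[int, list[tuple]],
                      known_positions: set[int] | None = None) -> ClassLabel:
    """Precedence rule A > B > C with supporting evidence.

    ``known_positions`` (residue numbers present in the topology) guards
    against classifying positions outside the model.
    """
    pos = record.position
    if known_positions is not None and pos not in known_positions:
        raise KeyError(f"position {pos} absent from topology")
    if pos in dna_evidence:
        ev = dna_evidence[pos]
        return ClassLabel("A", [_fmt(k) for _, k in ev],
                          sorted({s for s, _ in ev}, key=str))
    ev = atp_evidence.get(pos, []) + interface_ev.get(pos, [])
    if ev:
        return ClassLabel("B", [_fmt(k) for _, k in ev],
                          sorted({s for s, _ in ev}, key=str))
    return ClassLabel("C")


def mutation_report(catalog: list[MutationRecord], table: ContactTable,
                    topology: Topology | None = None) -> pd.DataFrame:
    """One row per catalog record with rule class, annotation and evidence."""
    dna_ev = dna_contact_evidence(table)
    atp_ev = nucleotide_contact_evidence(table)
    iface_ev = interface_evidence(table)
    known = None
    if topology is not None:
        known = {int(r) for r, c in zip(topology.res_id, topology.chain_id)
                 if c == "A"}
    rows = []
    for rec in catalog:
        lab = classify_mutation(rec, dna_ev, atp_ev, iface_ev, known)
        rows.append({
            "position": rec.position,
            "wild_type": rec.wild_type,
            "substitutions": "/".join(rec.substitutions),
            "phenotype": rec.phenotype,
            "rule_class": lab.label,
            "annotated_class": rec.paper_class,
            "agrees": (rec.paper_class is None) or lab.label == rec.paper_class,
            "evidence": "; ".join(sorted(set(lab.evidence))),
            "states": ",".join(str(s) for s in lab.states),
        })
    return pd.DataFrame(rows)
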
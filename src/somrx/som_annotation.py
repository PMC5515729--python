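"""Deriving site-of-metabolism (SOM) labels from reaction records.

Reaction corpora record whole transformations, not labelled atoms, so SOMs
must be derived.  Simple reactions are handled by a structure diff: the
maximum common substructure (MCS) of substrate and product is computed and
substrate atoms outside it, or inside it with a changed bonding environment,
are the reaction centers.  For dealkylations the heteroatom convention
applies: when the raw diff is a heteroatom (O, N, S) plus the alkyl carbon it
loses, the heteroatom alone is the SOM.  Complex reactions (ring formation,
opening, contraction, expansion) are handled by their reaction SMARTS
pattern: the designated center map atom of the pattern, matched onto the
substrate, defines the SOM.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chem_io import PatternRecord, ReactionRecord

logger = logging.getLogger(__name__)


class AmbiguousCenterError(ValueError):
    """Substrate and product share no usable common substructure."""


class PatternMatchError(ValueError):
    """A reaction pattern does not match the substrate."""


@dataclass(frozen=True)
class SomAnnotation:
    record_id: str
    som_atoms: tuple[int, ...]
    method: str  # {"mcs-diff", "pattern", "provided"}


_HETEROATOMS = frozenset(("O", "N", "S"))


def soms_by_mcs(substrate: Chem.Mol, product: Chem.Mol) -> list[int]:
    """Substrate reaction centers from the substrate/product structure diff.

    MCS flavor: connected, element-exact, bond-order-exact, ring bonds only
    match ring bonds — oxidation-state changes must break the mapping.
    """
    params = rdFMCS.MCSParameters()
    params.AtomTyper = rdFMCS.AtomCompare.CompareElements
    params.BondTyper = rdFMCS.BondCompare.CompareOrderExact
    params.BondCompareParameters.RingMatchesRingOnly = True
    result = rdFMCS.FindMCS([substrate, product], params)
    if result.numAtoms == 0:
        raise AmbiguousCenterError("no common substructure")
    query = Chem.MolFromSmarts(result.smartsString)
    sub_match = substrate.GetSubstructMatch(query)
    prod_match = product.GetSubstructMatch(query)
    if not sub_match or not prod_match:
        raise AmbiguousCenterError("MCS does not map back onto both structures")
    mapping = dict(zip(sub_match, prod_match))

    raw: set[int] = {a.GetIdx() for a in substrate.GetAtoms()
                     if a.GetIdx() not in mapping}
    for idx, pidx in mapping.items():
        a = substrate.GetAtomWithIdx(idx)
        b = product.GetAtomWithIdx(pidx)
        if a.GetDegree() != b.GetDegree() or a.GetTotalNumHs() != b.GetTotalNumHs():
            raw.add(idx)
    if not raw:
        raise AmbiguousCenterError("substrate and product are identical")
    return sorted(_apply_heteroatom_convention(substrate, raw, mapping))


def _apply_heteroatom_convention(substrate: Chem.Mol, raw: set[int],
                                 mapping: dict[int, int]) -> set[int]:
    """Collapse {heteroatom, leaving alkyl carbon} diffs onto the heteroatom."""
    hetero = {i for i in raw
              if substrate.GetAtomWithIdx(i).GetSymbol() in _HETEROATOMS}
    if not hetero:
        return raw
    removed_c = {
        i for i in raw
        if i not in mapping  # atom absent from the product
        and substrate.GetAtomWithIdx(i).GetSymbol() == "C"
        and any(nb.GetIdx() in hetero
                for nb in substrate.GetAtomWithIdx(i).GetNeighbors())
    }
    if removed_c and raw == hetero | removed_c:
        return hetero
    return raw


def pattern_changed_maps(pattern: PatternRecord) -> list[int]:
    """Atom-map numbers whose bonding changes between the two pattern sides.

    A mapped atom counts as changed if it disappears, or if its in-pattern
    degree, unmapped-neighbor count, bond orders to mapped neighbors, or
    ring closure pattern differ between the reactant and product templates.
    """
    rxn = pattern.reaction()

    def side_env(templates):
        env = {}
        for t in templates:
            for a in t.GetAtoms():
                mapno = a.GetAtomMapNum()
                if not mapno:
                    continue
                bonds = sorted(
                    (b.GetOtherAtom(a).GetAtomMapNum(), str(b.GetBondType()))
                    for b in a.GetBonds())
                env[mapno] = (len(bonds), bonds, a.IsInRing())
        return env

    r_env = side_env(rxn.GetReactants())
    p_env = side_env(rxn.GetProducts())
    changed = [m for m in sorted(r_env)
               if m not in p_env or r_env[m] != p_env[m]]
    return changed


def pattern_center_map(pattern: PatternRecord) -> int:
    """The designated reaction-center map atom (explicit, else first changed)."""
    if pattern.center_map is not None:
        return pattern.center_map
    changed = pattern_changed_maps(pattern)
    if not changed:
        raise PatternMatchError(
            f"pattern {pattern.pattern_id}: no changed mapped atom")
    return changed[0]


def soms_by_pattern(substrate: Chem.Mol, pattern: PatternRecord) -> list[int]:
    """Substrate atoms onto which the pattern's reaction-center map atom falls."""
    rxn = pattern.reaction()
    if rxn.GetNumReactantTemplates() != 1:
        raise PatternMatchError(
            f"pattern {pattern.pattern_id}: expected a single reactant template")
    template = rxn.GetReactantTemplate(0)
    center = pattern_center_map(pattern)
    tpl_idx = next((a.GetIdx() for a in template.GetAtoms()
                    if a.GetAtomMapNum() == center), None)
    if tpl_idx is None:
        raise PatternMatchError(
            f"pattern {pattern.pattern_id}: center map {center} not in template")
    matches = substrate.GetSubstructMatches(template, uniquify=True)
    if not matches:
        raise PatternMatchError(
            f"pattern {pattern.pattern_id} does not match the substrate")
    return sorted({match[tpl_idx] for match in matches})


def annotate_dataset(records: Sequence[ReactionRecord],
                     patterns: Sequence[PatternRecord]
                     ) -> tuple[list[SomAnnotation], Counter]:
    """SOM labels for a curated corpus; returns (annotations, method census).

    Explicit ``som_atoms`` take precedence, then the record's reaction
    pattern, then the MCS diff.  Records failing all three are dropped
    (counted under ``"failed"``).
    """
    by_id = {p.pattern_id: p for p in patterns}
    annotations: list[SomAnnotation] = []
    census: Counter = Counter()
    for rec in records:
        ann = _annotate_one(rec, by_id)
        if ann is None:
            census["failed"] += 1
            logger.warning("record %s: could not derive SOMs, dropped", rec.record_id)
            continue
        census[ann.method] += 1
        annotations.append(ann)
    return annotations, census


def _annotate_one(rec: ReactionRecord,
                  by_id: dict[str, PatternRecord]) -> SomAnnotation | None:
    if rec.som_atoms:
        return SomAnnotation(rec.record_id, tuple(rec.som_atoms), "provided")
    if rec.pattern_id and rec.pattern_id in by_id:
        try:
            soms = soms_by_pattern(rec.substrate(), by_id[rec.pattern_id])
            return SomAnnotation(rec.record_id, tuple(soms), "pattern")
        except PatternMatchError:
            pass
    try:
        products = rec.products()
        product = max(products, key=lambda m: m.GetNumAtoms())
        soms = soms_by_mcs(rec.substrate(), product)
        return SomAnnotation(rec.record_id, tuple(soms), "mcs-diff")
    except Exception:
        return None


def write_annotations(annotations: Sequence[SomAnnotation], path) -> None:
    from pathlib import Path
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("# record_id\tsom_atoms\tmethod\n")
        for a in annotations:
            fh.write(f"{a.record_id}\t{','.join(map(str, a.som_atoms))}\t{a.method}\n")
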
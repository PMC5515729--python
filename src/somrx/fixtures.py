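"""Deterministic synthetic reaction corpus with ground-truth reaction centers.

Real metabolic reaction corpora are licensed and cannot ship with the
package, so this module generates a small, fully labelled stand-in.  Eight
reaction classes are emulated — O-, N- and S-demethylation, aromatic
hydroxylation, phenol O-glucuronidation, methyl-ester hydrolysis, and the
two ring reactions cyclization (GABA-like aminoacid -> lactam) and ring
opening (N-alkylpiperidine -> amino acid).  Each class enumerates substrates
by decorating a handful of scaffold templates with benign substituents, so
reaction-center environments recur across records — the statistical
redundancy the similarity model exploits.  Products and SOM labels are
computed by applying the class's reaction SMARTS at the pattern's designated
center, which makes every record self-consistent by construction.

The pattern library also carries ring-contraction and ring-expansion
patterns written over mapped ring atoms, exactly as a rule curator would
state them for benzodiazepine contraction and ethynyl-cyclopentanol
expansion.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem

from .chem_io import (PatternRecord, ReactionRecord, write_patterns,
                      write_reactions)
from .predictor import check_applicability
from .som_annotation import soms_by_pattern

HOLDOUT_FRACTION = 0.2

#: reaction classes used to generate records: (class id, pattern, templates)
_TABLE_PATTERNS = [
    PatternRecord(
        "cyclization", "Cyclization",
        "[C:1]([NH2])[C:2][C:3][C:4](=O)O>>[C:1]1[C:2][C:3][C:4](=O)N1",
        center_map=1),
    PatternRecord(
        "ring_opening", "Ring opening",
        "[C:1][N:2]1[C:3][C:4][C:5][C:6][C:7]1>>[C:1][N:2][C:3][C:4][C:5][C:6][C:7](=O)O",
        center_map=7),
    PatternRecord(
        "ring_contraction", "Ring contraction",
        "[c:1]1[c:2][C:3]=[N:4][C:5](O)[C:6](=O)[N:7]1>>[c:1]1[c:2][C:3]=[N:4][C:5](=O)[N:7]1.[C:6]",
        center_map=6),
    PatternRecord(
        "ring_expansion", "Ring expansion",
        "[C:1]1[C:2][C:3][C:4][C:5]1(O)(C#C)>>[C:1]1[C:2][C:3][C:4]C[C:5]1(O)",
        center_map=5),
]

_SIMPLE_PATTERNS = [
    PatternRecord("O_demethyl", "O-demethylation",
                  "[c:1][O:2][CH3]>>[c:1][O:2]", center_map=2),
    PatternRecord("N_demethyl", "N-demethylation",
                  "[c:1][NX3:2][CH3]>>[c:1][N:2]", center_map=2),
    PatternRecord("S_demethyl", "S-demethylation",
                  "[c:1][S:2][CH3]>>[c:1][S:2]", center_map=2),
    PatternRecord("arom_hydroxyl", "Aromatic hydroxylation",
                  "[cH:1]>>[c:1]O", center_map=1),
    PatternRecord("O_glucuronidation", "Phenol O-glucuronidation",
                  "[c:1][OX2H:2]>>[c:1][O:2]C1OC(C(=O)O)C(O)C(O)C1O",
                  center_map=2),
    PatternRecord("ester_hydrolysis", "Methyl-ester hydrolysis",
                  "[C:1](=[O:2])O[CH3]>>[C:1](=[O:2])O", center_map=1),
]

#: per-class substrate templates; "{R}" is the decoration point
_CLASS_TEMPLATES: dict[str, list[str]] = {
    "O_demethyl": ["COc1ccc({R})cc1", "COc1cccc({R})c1", "COc1ccc(C{R})cc1"],
    "N_demethyl": ["CNc1ccc({R})cc1", "CNc1cccc({R})c1", "CNc1ccc(C{R})cc1"],
    "S_demethyl": ["CSc1ccc({R})cc1", "CSc1cccc({R})c1", "CSc1ccc(C{R})cc1"],
    "arom_hydroxyl": ["Cc1ccc({R})cc1", "CCc1ccc({R})cc1", "CC(C)c1ccc({R})cc1"],
    "O_glucuronidation": ["Oc1ccc({R})cc1", "Oc1cccc({R})c1", "Oc1ccc(C{R})cc1"],
    "ester_hydrolysis": ["COC(=O)c1ccc({R})cc1", "COC(=O)C{R}", "COC(=O)CC{R}"],
    "cyclization": ["NC({R})CCC(=O)O", "NCC({R})CC(=O)O", "NCCC({R})C(=O)O"],
    "ring_opening": ["CN1CCC({R})CC1", "CCN1CCC({R})CC1", "CN1CCCC({R})C1"],
}

#: benign substituents: no group reactive under any fixture class
_SUBSTITUENTS = ["C", "CC", "CCC", "C(C)C", "F", "Cl", "Br",
                 "C(F)(F)F", "C(C)(C)C", "CC(C)C"]

#: alkyl-only decoration for aliphatic scaffolds (halogens alpha to N/O
#: would be chemically implausible substrates)
_ALKYL_SUBSTITUENTS = ["C", "CC", "CCC", "C(C)C", "C(C)(C)C", "CC(C)C",
                       "CCCC", "CC(C)CC", "CCC(C)C", "CCCCC"]
_ALKYL_ONLY_CLASSES = frozenset({"cyclization", "ring_opening",
                                 "ester_hydrolysis"})

#: unreactive decoys: saturated hydrocarbons and simple ethers
_DECOYS = ["CCCCCC", "CC(C)CCC", "C1CCCCC1", "CC1CCCCC1", "CCC(C)CC",
           "CCOCC", "C1CCOC1C", "CC(C)OC(C)C", "CCCC(C)CC", "CC1CCC(C)CC1"]


@dataclass
class FixtureManifest:
    seed: int
    n_per_class: int
    reaction_classes: list[str]
    records: list[ReactionRecord]
    patterns: list[PatternRecord]
    holdout_ids: list[str]
    decoys: list[str] = field(default_factory=list)

    @property
    def training_records(self) -> list[ReactionRecord]:
        hold = set(self.holdout_ids)
        return [r for r in self.records if r.record_id not in hold]

    @property
    def holdout_records(self) -> list[ReactionRecord]:
        hold = set(self.holdout_ids)
        return [r for r in self.records if r.record_id in hold]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for r in self.records:
            soms = ",".join(map(str, r.som_atoms or []))
            h.update(f"{r.record_id}\t{r.reaction_smiles}\t{r.pattern_id}"
                     f"\t{soms}\n".encode())
        h.update(("|".join(self.holdout_ids) + "|".join(self.decoys)).encode())
        return h.hexdigest()


def builtin_patterns() -> list[PatternRecord]:
    """The built-in reaction SMARTS library (ring reactions + simple classes)."""
    return [PatternRecord(p.pattern_id, p.name, p.reaction_smarts, p.center_map)
            for p in _TABLE_PATTERNS + _SIMPLE_PATTERNS]


class VocabularyExhaustedError(RuntimeError):
    """More records requested per class than decorated substrates exist."""


def _enumerate_substrates(class_id: str, rng: random.Random,
                          n: int) -> list[str]:
    """n unique canonical substrates for a class, deterministically chosen."""
    subs = (_ALKYL_SUBSTITUENTS if class_id in _ALKYL_ONLY_CLASSES
            else _SUBSTITUENTS)
    combos = [(t, s) for t in _CLASS_TEMPLATES[class_id] for s in subs]
    rng.shuffle(combos)
    out: list[str] = []
    seen: set[str] = set()
    for template, sub in combos:
        mol = Chem.MolFromSmiles(template.format(R=sub))
        if mol is None:
            continue
        smi = Chem.MolToSmiles(mol)
        if smi in seen:
            continue
        seen.add(smi)
        out.append(smi)
        if len(out) == n:
            return out
    raise VocabularyExhaustedError(
        f"class {class_id}: only {len(out)} unique substrates available, "
        f"{n} requested; use a smaller n_per_class")


def generate_dataset(seed: int = 7, n_per_class: int = 10) -> FixtureManifest:
    """Generate the labelled fixture corpus (identical seed => identical output)."""
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = random.Random(seed)
    patterns = builtin_patterns()
    by_id = {p.pattern_id: p for p in patterns}
    records: list[ReactionRecord] = []
    classes = sorted(_CLASS_TEMPLATES)
    for class_id in classes:
        pattern = by_id[class_id]
        for i, smi in enumerate(_enumerate_substrates(class_id, rng, n_per_class)):
            mol = Chem.MolFromSmiles(smi)  # canonical atom order
            soms = soms_by_pattern(mol, pattern)
            som = soms[rng.randrange(len(soms))] if class_id == "arom_hydroxyl" \
                else soms[0]
            ok, products = check_applicability(mol, som, pattern)
            if not ok:  # pragma: no cover - classes are built to apply
                raise RuntimeError(f"{class_id}: pattern failed on {smi}")
            product_smiles = ".".join(Chem.MolToSmiles(p) for p in products[:1]) \
                if class_id != "arom_hydroxyl" else Chem.MolToSmiles(products[0])
            record_soms = sorted(soms) if class_id != "arom_hydroxyl" else [som]
            records.append(ReactionRecord(
                record_id=f"{class_id}_{i:03d}",
                reaction_smiles=f"{smi}>>{product_smiles}",
                pattern_id=class_id,
                som_atoms=record_soms))
    n_holdout = max(1, round(n_per_class * HOLDOUT_FRACTION))
    holdout: list[str] = []
    for class_id in classes:
        ids = [r.record_id for r in records if r.pattern_id == class_id]
        holdout.extend(rng.sample(ids, n_holdout))
    decoys = list(_DECOYS)
    return FixtureManifest(seed=seed, n_per_class=n_per_class,
                           reaction_classes=classes, records=records,
                           patterns=patterns, holdout_ids=sorted(holdout),
                           decoys=decoys)


def write_fixture_files(manifest: FixtureManifest, out_dir: str | Path) -> dict:
    """Write reactions.tsv, patterns.tsv, holdout.tsv, decoys.smi, manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_reactions(manifest.records, out / "reactions.tsv")
    write_patterns(manifest.patterns, out / "patterns.tsv")
    with (out / "holdout.tsv").open("w", encoding="utf-8") as fh:
        fh.write("# record_id\n")
        for rid in manifest.holdout_ids:
            fh.write(rid + "\n")
    with (out / "decoys.smi").open("w", encoding="utf-8") as fh:
        for i, smi in enumerate(manifest.decoys):
            fh.write(f"{smi} decoy{i}\n")
    meta = {
        "seed": manifest.seed,
        "n_per_class": manifest.n_per_class,
        "reaction_classes": manifest.reaction_classes,
        "n_records": len(manifest.records),
        "n_holdout": len(manifest.holdout_ids),
        "content_hash": manifest.content_hash(),
    }
    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return meta
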
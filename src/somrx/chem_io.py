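"""Reading, writing and curation of reaction corpora and pattern libraries.

Tabular formats are UTF-8 TSV with ``#`` comment lines.  Reaction records
carry a reaction SMILES (``substrate(s)>>product(s)``), an optional reaction
pattern id and optional ground-truth site-of-metabolism (SOM) atom indices
(0-based heavy-atom indices of the first substrate, in canonical order).
Structures round-trip through RDKit canonical SMILES; metabolite structures
are written as V2000 SDF.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import rdChemReactions

if TYPE_CHECKING:  # pragma: no cover
    from .predictor import MetabolitePrediction, SitePrediction

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when a file yields no usable records."""


@dataclass
class ReactionRecord:
    """One curated metabolic reaction."""

    record_id: str
    reaction_smiles: str
    pattern_id: str | None = None
    som_atoms: list[int] | None = None

    _substrate: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def substrates(self) -> list[Chem.Mol]:
        lhs = self.reaction_smiles.split(">>")[0]
        mols = [Chem.MolFromSmiles(s) for s in lhs.split(".")]
        return [m for m in mols if m is not None]

    def products(self) -> list[Chem.Mol]:
        rhs = self.reaction_smiles.split(">>")[1]
        mols = [Chem.MolFromSmiles(s) for s in rhs.split(".")]
        return [m for m in mols if m is not None]

    def substrate(self) -> Chem.Mol:
        """The largest reactant by heavy-atom count; cofactors are ignored."""
        if self._substrate is None:
            subs = self.substrates()
            if not subs:
                raise FormatError(f"record {self.record_id}: no parseable substrate")
            self._substrate = max(subs, key=lambda m: m.GetNumAtoms())
        return self._substrate


@dataclass
class PatternRecord:
    """A reaction SMARTS transformation with a designated reaction-center map atom."""

    pattern_id: str
    name: str
    reaction_smarts: str
    center_map: int | None = None  # atom-map number of the reaction center

    _rxn: rdChemReactions.ChemicalReaction | None = field(
        default=None, repr=False, compare=False)

    def reaction(self) -> rdChemReactions.ChemicalReaction:
        if self._rxn is None:
            rxn = _compile_reaction(self.reaction_smarts)
            if rxn is None:
                raise FormatError(
                    f"pattern {self.pattern_id}: invalid reaction SMARTS")
            self._rxn = rxn
        return self._rxn


def _compile_reaction(smarts: str) -> rdChemReactions.ChemicalReaction | None:
    try:
        rxn = rdChemReactions.ReactionFromSmarts(smarts)
    except Exception:
        return None
    if rxn is None or rxn.GetNumReactantTemplates() == 0 or \
            rxn.GetNumProductTemplates() == 0:
        return None
    mapped_r = any(a.GetAtomMapNum() for t in rxn.GetReactants() for a in t.GetAtoms())
    mapped_p = any(a.GetAtomMapNum() for t in rxn.GetProducts() for a in t.GetAtoms())
    if not (mapped_r and mapped_p):
        return None
    return rxn


def _parse_reaction_smiles(rsmi: str) -> tuple[list[Chem.Mol], list[Chem.Mol]] | None:
    parts = rsmi.split(">>")
    if len(parts) != 2:
        return None
    subs = [Chem.MolFromSmiles(s) for s in parts[0].split(".") if s]
    prods = [Chem.MolFromSmiles(s) for s in parts[1].split(".") if s]
    if not subs or not prods or any(m is None for m in subs + prods):
        return None
    return subs, prods


def read_reactions(path: str | Path, dialect: str = "tsv") -> list[ReactionRecord]:
    """Read reaction records; unparseable lines are skipped with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect != "tsv":
        raise NotImplementedError(f"dialect {dialect!r} not supported")
    records: list[ReactionRecord] = []
    skipped = 0
    with path.open(encoding="utf-8") as fh:
        reader = csv.reader(
            (ln for ln in fh if ln.strip() and not ln.startswith("#")),
            delimiter="\t")
        for row in reader:
            if len(row) < 2:
                skipped += 1
                continue
            record_id, rsmi = row[0].strip(), row[1].strip()
            if _parse_reaction_smiles(rsmi) is None:
                logger.warning("skipping unparseable reaction %r", record_id)
                skipped += 1
                continue
            pattern_id = row[2].strip() or None if len(row) > 2 else None
            som_atoms = None
            if len(row) > 3 and row[3].strip():
                try:
                    som_atoms = [int(t) for t in row[3].split(",")]
                except ValueError:
                    logger.warning("skipping record %r: bad som_atoms", record_id)
                    skipped += 1
                    continue
            records.append(ReactionRecord(record_id, rsmi, pattern_id, som_atoms))
    if not records:
        raise FormatError(f"{path}: no parseable reaction records ({skipped} skipped)")
    if skipped:
        logger.warning("%s: skipped %d unparseable lines", path, skipped)
    return records


def canonical_reaction_smiles(rsmi: str) -> str | None:
    """Canonical reaction identity: each side canonicalized, sorted, dot-joined."""
    parsed = _parse_reaction_smiles(rsmi)
    if parsed is None:
        return None
    subs, prods = parsed
    lhs = ".".join(sorted(Chem.MolToSmiles(m) for m in subs))
    rhs = ".".join(sorted(Chem.MolToSmiles(m) for m in prods))
    return f"{lhs}>>{rhs}"


def _has_dummy_or_radical(mols: Iterable[Chem.Mol]) -> bool:
    for m in mols:
        for a in m.GetAtoms():
            if a.GetAtomicNum() == 0 or a.GetNumRadicalElectrons() > 0:
                return True
    return False


def curate_reactions(records: Sequence[ReactionRecord]
                     ) -> tuple[list[ReactionRecord], dict[str, int]]:
    """Apply the five corpus-curation filters; returns (kept, per-filter counts).

    Filters: duplicate reactions (canonical reaction identity), dummy-atom or
    radical structures, unparseable structures, ambiguous reaction centers
    (no pattern id and an empty structure diff), and single-element
    reactants/products.
    """
    from .som_annotation import AmbiguousCenterError, soms_by_mcs

    counts = {"duplicate": 0, "dummy_or_radical": 0, "invalid": 0,
              "ambiguous_center": 0, "single_element": 0}
    seen: set[str] = set()
    kept: list[ReactionRecord] = []
    for rec in records:
        parsed = _parse_reaction_smiles(rec.reaction_smiles)
        if parsed is None:
            counts["invalid"] += 1
            continue
        subs, prods = parsed
        canon = canonical_reaction_smiles(rec.reaction_smiles)
        if canon in seen:
            counts["duplicate"] += 1
            continue
        if _has_dummy_or_radical(subs + prods):
            counts["dummy_or_radical"] += 1
            continue
        if any(m.GetNumAtoms() == 1 for m in subs + prods):
            counts["single_element"] += 1
            continue
        if rec.pattern_id is None and rec.som_atoms is None:
            try:
                soms = soms_by_mcs(rec.substrate(), max(prods, key=lambda m: m.GetNumAtoms()))
            except AmbiguousCenterError:
                soms = []
            if not soms:
                counts["ambiguous_center"] += 1
                continue
        seen.add(canon)
        kept.append(rec)
    return kept, counts


def read_patterns(path: str | Path) -> list[PatternRecord]:
    """Read a pattern library TSV (pattern_id, name, reaction_smarts[, center_map])."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    patterns: list[PatternRecord] = []
    with path.open(encoding="utf-8") as fh:
        reader = csv.reader(
            (ln for ln in fh if ln.strip() and not ln.startswith("#")),
            delimiter="\t")
        for row in reader:
            if len(row) < 3:
                continue
            pid, name, smarts = row[0].strip(), row[1].strip(), row[2].strip()
            if _compile_reaction(smarts) is None:
                logger.warning("rejecting pattern %r: SMARTS does not compile", pid)
                continue
            center = int(row[3]) if len(row) > 3 and row[3].strip() else None
            patterns.append(PatternRecord(pid, name, smarts, center))
    if not patterns:
        raise FormatError(f"{path}: no compilable patterns")
    return patterns


def write_patterns(patterns: Sequence[PatternRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("# pattern_id\tname\treaction_smarts\tcenter_map\n")
        for p in patterns:
            center = "" if p.center_map is None else str(p.center_map)
            fh.write(f"{p.pattern_id}\t{p.name}\t{p.reaction_smarts}\t{center}\n")


def write_reactions(records: Sequence[ReactionRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("# record_id\treaction_smiles\tpattern_id\tsom_atoms\n")
        for r in records:
            soms = ",".join(str(i) for i in r.som_atoms) if r.som_atoms else ""
            fh.write(f"{r.record_id}\t{r.reaction_smiles}\t{r.pattern_id or ''}\t{soms}\n")


def write_predictions(sites: Sequence["SitePrediction"],
                      metabolites: Sequence["MetabolitePrediction"],
                      out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.sites.tsv`` and ``<prefix>.metabolites.sdf``."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sites_path = prefix.with_name(prefix.name + ".sites.tsv")
    sdf_path = prefix.with_name(prefix.name + ".metabolites.sdf")

    with sites_path.open("w", encoding="utf-8") as fh:
        fh.write("molecule_id\tatom_index\telement\tm\tn\tx\tr\tp\tcategory\trank\n")
        for s in sites:
            fh.write(f"{s.molecule_id}\t{s.atom_index}\t{s.element}\t{s.m}\t{s.n}"
                     f"\t{s.x}\t{s.r:.6f}\t{s.p:.6f}\t{s.category}\t{s.rank}\n")

    writer = Chem.SDWriter(str(sdf_path))
    writer.SetForceV3000(False)
    for met in metabolites:
        mol = Chem.MolFromSmiles(met.product_smiles)
        if mol is None:  # pragma: no cover - products are pre-validated
            continue
        mol.SetProp("_Name", f"{met.parent_id}_M{met.rank}")
        mol.SetProp("parent_id", met.parent_id)
        mol.SetProp("site_atom", str(met.site_atom))
        mol.SetProp("pattern_id", met.pattern_id)
        mol.SetProp("p", f"{met.site_p:.6f}")
        mol.SetProp("rank", str(met.rank))
        writer.write(mol)
    writer.close()
    return sites_path, sdf_path


def read_molecules(path: str | Path) -> list[tuple[str, Chem.Mol]]:
    """Read query molecules from ``.smi``/``.txt`` (SMILES [id]) or ``.sdf``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[tuple[str, Chem.Mol]] = []
    if path.suffix.lower() == ".sdf":
        for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
            if mol is None:
                logger.warning("skipping unreadable SDF record %d", i)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
            out.append((name or f"mol{i}", mol))
    else:
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                mol = Chem.MolFromSmiles(parts[0])
                if mol is None:
                    logger.warning("skipping unparseable SMILES on line %d", i + 1)
                    continue
                out.append((parts[1] if len(parts) > 1 else f"mol{i}", mol))
    if not out:
        raise FormatError(f"{path}: no parseable molecules")
    return out


def canonical_mol(smiles: str) -> Chem.Mol:
    """Parse and return the molecule with canonical atom ordering."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FormatError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))
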
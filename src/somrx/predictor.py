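"""End-to-end site-of-metabolism and metabolite prediction.

For each heavy atom of a query molecule the two fingerprint databases are
searched: m similar substrate-atom environments and n similar reaction-center
environments (occurrence-weighted).  Raw similarity is then corrected for
chemistry: each center hit carries reaction patterns, and a hit whose
patterns all fail to apply at the query atom is re-classified as dissimilar
(x).  The occurrence ratio

    r_i = (n - x) / (m - x)

estimates the fraction of genuinely reactive look-alike environments, and is
normalized per molecule to p = r_i / max(r_i), the site's metabolic
probability (the top site of any molecule with evidence scores exactly 1.0).
Sites are binned into the qualitative categories very unlikely / unlikely /
likely / very likely and ranked; metabolite structures are generated by
running the applicable patterns anchored at the top-ranked sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from rdkit import Chem

from .chem_io import PatternRecord
from .database import FingerprintDatabasePair, query
from .fingerprint import DEFAULT_ALPHABET, molecule_fingerprints
from .similarity import SimilarityParams
from .som_annotation import pattern_center_map

logger = logging.getLogger(__name__)

#: qualitative bins for the normalized occurrence ratio p
CATEGORY_BINS = (
    (0.15, "very unlikely"),
    (0.33, "unlikely"),
    (0.66, "likely"),
    (1.00, "very likely"),
)

DEFAULT_TOP_K = 3


@dataclass
class SitePrediction:
    molecule_id: str
    atom_index: int
    element: str
    m: int
    n: int
    x: int
    r: float
    p: float = 0.0
    category: str = "very unlikely"
    rank: int = 0


@dataclass
class MetabolitePrediction:
    parent_id: str
    product_smiles: str
    site_atom: int
    pattern_id: str
    support: int
    site_p: float
    rank: int = 0


def categorize(p: float) -> str:
    """Qualitative metabolic-likelihood bin for a normalized ratio p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"normalized occurrence ratio {p} outside [0, 1]")
    for upper, name in CATEGORY_BINS:
        if p < upper:
            return name
    return "very likely"  # p == 1.0: the molecule's top-ranked site


def check_applicability(mol: Chem.Mol, atom_index: int, pattern: PatternRecord
                        ) -> tuple[bool, list[Chem.Mol]]:
    """Can this pattern transform the molecule *at this atom*?

    Applicable iff a reactant-template match lands the pattern's designated
    reaction-center map atom on ``atom_index`` and at least one resulting
    product set sanitizes.  Returns all sanitized products from such matches.
    """
    try:
        rxn = pattern.reaction()
        center = pattern_center_map(pattern)
    except Exception:
        return False, []
    products: list[Chem.Mol] = []
    seen: set[str] = set()
    try:
        outcomes = rxn.RunReactants((mol,))
    except Exception:
        return False, []
    for product_set in outcomes:
        anchored = any(
            a.HasProp("old_mapno") and a.GetIntProp("old_mapno") == center
            and a.HasProp("react_atom_idx")
            and a.GetIntProp("react_atom_idx") == atom_index
            for p in product_set for a in p.GetAtoms())
        if not anchored:
            continue
        sane = []
        for p in product_set:
            try:
                Chem.SanitizeMol(p)
            except Exception:
                sane = None
                break
            sane.append(p)
        if sane is None:
            continue
        for p in sane:
            smi = Chem.MolToSmiles(p)
            if smi not in seen:
                seen.add(smi)
                products.append(p)
    return bool(products), products


@dataclass
class _SiteHits:
    """Per-atom center-db hits with resolved applicability (cached for reuse)."""
    applicable: dict[str, tuple[int, list[str]]] = field(default_factory=dict)
    # pattern_id -> (summed occurrence count, product SMILES)


def predict_sites(mol: Chem.Mol, db: FingerprintDatabasePair,
                  patterns: Sequence[PatternRecord],
                  params: SimilarityParams | None = None,
                  molecule_id: str = "query",
                  _hits_out: dict[int, _SiteHits] | None = None
                  ) -> list[SitePrediction]:
    """Score every heavy atom of the query molecule (m, n, x, r, p, rank)."""
    if not db.substrate_db:
        raise ValueError("empty fingerprint database")
    if mol.GetNumAtoms() == 0:
        return []
    params = params or SimilarityParams(n_layers=db.n_layers)
    by_id = {p.pattern_id: p for p in patterns}
    fps = molecule_fingerprints(mol, db.n_layers, DEFAULT_ALPHABET, molecule_id)
    applicability_cache: dict[tuple[str, int], tuple[bool, list[str]]] = {}

    def applicable(pattern_id: str, atom: int) -> tuple[bool, list[str]]:
        key = (pattern_id, atom)
        if key not in applicability_cache:
            pattern = by_id.get(pattern_id)
            if pattern is None:
                # unpatterned center records cannot be checked and are
                # accepted as-is (no correction evidence against them)
                applicability_cache[key] = (True, [])
            else:
                ok, prods = check_applicability(mol, atom, pattern)
                applicability_cache[key] = (ok, [Chem.MolToSmiles(p) for p in prods])
        return applicability_cache[key]

    sites: list[SitePrediction] = []
    for fp in fps:
        atom = fp.root_atom
        m_hits, n_hits = query(db, fp, params)
        m = sum(e.occurrence_count for e in m_hits)
        n = sum(e.occurrence_count for e in n_hits)
        x = 0
        hits = _SiteHits()
        for entry in n_hits:
            entry_ok = False
            for pid, count in entry.pattern_counts.items():
                ok, prods = applicable(pid, atom)
                if ok:
                    entry_ok = True
                    acc = hits.applicable.setdefault(pid, (0, prods))
                    hits.applicable[pid] = (acc[0] + count, acc[1] or prods)
            if not entry_ok:
                x += entry.occurrence_count
        r = (n - x) / (m - x) if m > x else 0.0
        logger.debug("%s atom %d: m=%d n=%d x=%d r=%.4f",
                     molecule_id, atom, m, n, x, r)
        if _hits_out is not None:
            _hits_out[atom] = hits
        sites.append(SitePrediction(
            molecule_id, atom, mol.GetAtomWithIdx(atom).GetSymbol(), m, n, x, r))

    r_max = max(s.r for s in sites)
    for s in sites:
        s.p = s.r / r_max if r_max > 0 else 0.0
        s.category = categorize(s.p)
    for rank, s in enumerate(sorted(sites, key=lambda s: (-s.p, s.atom_index)), 1):
        s.rank = rank
    return sites


def generate_metabolites(mol: Chem.Mol, sites: Sequence[SitePrediction],
                         hits: dict[int, _SiteHits],
                         top_k: int = DEFAULT_TOP_K) -> list[MetabolitePrediction]:
    """Products of the applicable patterns at the top-k ranked reactive sites.

    Deduplicated by canonical product SMILES (symmetric sites collapse);
    ordered by generating-site rank, then support (occurrence count of the
    generating center records), then SMILES.
    """
    raw: dict[str, MetabolitePrediction] = {}
    for site in sites:
        if site.rank > top_k or site.p <= 0.0:
            continue
        site_hits = hits.get(site.atom_index)
        if site_hits is None:
            continue
        for pid, (support, product_smiles) in site_hits.applicable.items():
            for smi in product_smiles:
                prev = raw.get(smi)
                if prev is None:
                    raw[smi] = MetabolitePrediction(
                        site.molecule_id, smi, site.atom_index, pid,
                        support, site.p)
                else:
                    prev.support += support
    site_rank = {s.atom_index: s.rank for s in sites}
    ordered = sorted(raw.values(),
                     key=lambda m: (site_rank.get(m.site_atom, 1 << 30),
                                    -m.support, m.product_smiles))
    for i, met in enumerate(ordered, 1):
        met.rank = i
    return ordered


def predict(mol: Chem.Mol, db: FingerprintDatabasePair,
            patterns: Sequence[PatternRecord],
            params: SimilarityParams | None = None,
            top_k: int = DEFAULT_TOP_K, molecule_id: str = "query"
            ) -> tuple[list[SitePrediction], list[MetabolitePrediction]]:
    """Full workflow: fingerprint, search, correct, normalize, generate."""
    hits: dict[int, _SiteHits] = {}
    sites = predict_sites(mol, db, patterns, params, molecule_id, _hits_out=hits)
    metabolites = generate_metabolites(mol, sites, hits, top_k)
    return sites, metabolites
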
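"""Compound-library curation: standardization, selection funnel, flags.

Implements the structure-handling side of the screen: SDF/SMILES ingestion,
largest-fragment standardization with InChIKey generation, the ordered
selection funnel (availability >= 2 mg, heavy-atom count >= 25, overlap
removal against a reference key set), MaxMin diversity picking on Morgan
fingerprints, PAINS substructure flagging, and the lysosomotropism
physicochemical rule (logP > 2 and basic pKa in [6.5, 11]).

Predicted logP/pKa values are consumed from a sidecar table, never computed
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams
from rdkit.DataStructs import BulkTanimotoSimilarity
from rdkit.SimDivFilters.rdSimDivPickers import MaxMinPicker

logger = logging.getLogger(__name__)

AVAILABLE_FIELD = "available"


@dataclass
class CompoundRecord:
    """One library compound with its standardized structure and annotations."""

    identifier: str
    raw_structure: Chem.Mol
    available_mg: float | None = None
    standardized: Chem.Mol | None = None
    inchikey: str | None = None
    descriptors: dict = field(default_factory=dict)
    pains: list[str] | None = None
    lysosomotropic_like: bool | None = None


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def read_sdf(path: str | Path, id_field: str | None = None,
             available_field: str = AVAILABLE_FIELD) -> list[CompoundRecord]:
    """Read compound records from a V2000 SDF file.

    Unreadable records are skipped with a position-stamped log entry.  The
    identifier comes from ``id_field`` (or the molecule title), the available
    amount in mg from ``available_field`` when present.
    """
    records: list[CompoundRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for pos, mol in enumerate(supplier):
        if mol is None:
            logger.warning("read_sdf: unreadable record at position %d in %s",
                           pos, path)
            continue
        if id_field and mol.HasProp(id_field):
            ident = mol.GetProp(id_field)
        else:
            ident = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record_{pos}"
        avail = None
        if mol.HasProp(available_field):
            try:
                avail = float(mol.GetProp(available_field))
            except ValueError:
                logger.warning("read_sdf: bad %r value for %s",
                               available_field, ident)
        records.append(CompoundRecord(ident, mol, avail))
    return records


def read_smiles(path: str | Path, sep: str = "\t") -> list[CompoundRecord]:
    """Read records from a SMILES table (smiles, identifier[, available_mg])."""
    df = pd.read_csv(path, sep=sep)
    records = []
    for pos, row in df.iterrows():
        mol = Chem.MolFromSmiles(row.iloc[0])
        if mol is None:
            logger.warning("read_smiles: unparseable SMILES at row %d", pos)
            continue
        avail = float(row["available_mg"]) if "available_mg" in df.columns else None
        records.append(CompoundRecord(str(row.iloc[1]), mol, avail))
    return records


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Largest connected fragment; ties broken by heavy-atom count, then exact
    mass, then canonical SMILES (lexicographic), so the choice is stable."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda m: (m.GetNumHeavyAtoms(),
                                     Descriptors.ExactMolWt(m),
                                     Chem.MolToSmiles(m)))


def compute_descriptors(mol: Chem.Mol) -> dict:
    """The descriptor panel used to characterise the library."""
    return {
        "MW": Descriptors.MolWt(mol),
        "NumHA": mol.GetNumHeavyAtoms(),
        "logP": Crippen.MolLogP(mol),
        "TPSA": rdMolDescriptors.CalcTPSA(mol),
        "FrCsp3": rdMolDescriptors.CalcFractionCSP3(mol),
        "NumHAcc": Lipinski.NumHAcceptors(mol),
        "NumHDon": Lipinski.NumHDonors(mol),
    }


def standardize_record(record: CompoundRecord) -> CompoundRecord:
    """Standardize one record in place: largest fragment, InChIKey, descriptors.

    A failing InChIKey leaves ``inchikey`` as None and is logged, never
    silently dropped.  Idempotent: re-standardizing a standardized record is a
    no-op.
    """
    base = record.standardized if record.standardized is not None \
        else record.raw_structure
    frag = largest_fragment(base)
    Chem.SanitizeMol(frag)
    record.standardized = frag
    try:
        key = Chem.MolToInchiKey(frag)
        record.inchikey = key if key else None
    except Exception:  # InChI generation can fail on exotic structures
        record.inchikey = None
    if record.inchikey is None:
        logger.warning("standardize_record: InChIKey generation failed for %s",
                       record.identifier)
    record.descriptors = compute_descriptors(frag)
    return record


def standardize_and_key(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """Standardize every record (see :func:`standardize_record`)."""
    return [standardize_record(r) for r in records]


# ---------------------------------------------------------------------------
# the selection funnel
# ---------------------------------------------------------------------------

STAGES = ("input", "availability", "size", "overlap")


@dataclass
class FunnelReport:
    """Ordered per-stage survivor counts and each record's stage of exit."""

    stage_counts: dict[str, int]
    exit_stage: dict[str, str | None]  # identifier -> stage dropped at (None = kept)
    kept: list[CompoundRecord]
    n_missing_availability: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stage": list(self.stage_counts),
            "n_remaining": list(self.stage_counts.values()),
        })


def funnel(records: list[CompoundRecord],
           reference_keys: set[str] = frozenset(),
           min_mg: float = 2.0, min_heavy: int = 25) -> FunnelReport:
    """Apply the ordered selection funnel.

    Stages, in order: input count; availability (keep available_mg >= min_mg;
    a missing amount fails and is counted separately); size (keep NumHA >=
    min_heavy, boundary inclusive); overlap (drop records whose InChIKey is in
    ``reference_keys``, exact case-sensitive string match).
    """
    exit_stage: dict[str, str | None] = {}
    n_missing = 0

    kept = list(records)
    counts = {"input": len(kept)}

    survivors = []
    for r in kept:
        if r.available_mg is None:
            n_missing += 1
            exit_stage[r.identifier] = "availability"
        elif r.available_mg >= min_mg:
            survivors.append(r)
        else:
            exit_stage[r.identifier] = "availability"
    kept = survivors
    counts["availability"] = len(kept)

    survivors = []
    for r in kept:
        numha = r.descriptors.get("NumHA") if r.descriptors else None
        if numha is None:
            numha = (r.standardized or r.raw_structure).GetNumHeavyAtoms()
        if numha >= min_heavy:
            survivors.append(r)
        else:
            exit_stage[r.identifier] = "size"
    kept = survivors
    counts["size"] = len(kept)

    survivors = []
    for r in kept:
        if r.inchikey is not None and r.inchikey in reference_keys:
            exit_stage[r.identifier] = "overlap"
        else:
            survivors.append(r)
            exit_stage[r.identifier] = None
    kept = survivors
    counts["overlap"] = len(kept)

    return FunnelReport(counts, exit_stage, kept, n_missing)


# ---------------------------------------------------------------------------
# diversity selection
# ---------------------------------------------------------------------------

def morgan_fingerprints(mols, radius: int = 2, n_bits: int = 2048):
    """Morgan (ECFP-like) bit fingerprints for a list of molecules."""
    gen = AllChem.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return [gen.GetFingerprint(m) for m in mols]


def diversity_select(records: list[CompoundRecord], n_pick: int,
                     radius: int = 2, n_bits: int = 2048,
                     seed: int = 0) -> list[CompoundRecord]:
    """MaxMin (lazy greedy farthest-point) diversity selection.

    Picks ``n_pick`` records maximising the minimum pairwise Tanimoto distance
    of their Morgan fingerprints; deterministic for a given seed.  Returns all
    records when ``n_pick`` is at least the pool size.
    """
    if n_pick <= 0:
        raise ValueError("n_pick must be >= 1")
    if n_pick >= len(records):
        return list(records)
    mols = [r.standardized or r.raw_structure for r in records]
    fps = morgan_fingerprints(mols, radius=radius, n_bits=n_bits)
    picker = MaxMinPicker()
    idx = picker.LazyBitVectorPick(fps, len(fps), n_pick, seed=seed)
    return [records[i] for i in idx]


def min_pairwise_tanimoto_distance(records: list[CompoundRecord],
                                   radius: int = 2, n_bits: int = 2048) -> float:
    """Smallest pairwise Tanimoto distance within a record set."""
    mols = [r.standardized or r.raw_structure for r in records]
    fps = morgan_fingerprints(mols, radius=radius, n_bits=n_bits)
    best = 1.0
    for i in range(1, len(fps)):
        sims = BulkTanimotoSimilarity(fps[i], fps[:i])
        best = min(best, min(1.0 - s for s in sims))
    return best


# ---------------------------------------------------------------------------
# structure flags
# ---------------------------------------------------------------------------

_pains_catalog = None


def _get_pains_catalog() -> FilterCatalog:
    global _pains_catalog
    if _pains_catalog is None:
        params = FilterCatalogParams()
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
        _pains_catalog = FilterCatalog(params)
    return _pains_catalog


def pains_flags(mol: Chem.Mol) -> list[str]:
    """Names of matched PAINS substructure patterns (empty list = clean)."""
    if mol is None:
        raise ValueError("pains_flags requires a valid molecule")
    catalog = _get_pains_catalog()
    return [entry.GetDescription()
            for entry in catalog.GetMatches(mol)]


def lysosomotropic_like(logp: float, pka: float | None) -> bool | None:
    """Lysosomotropism physchem rule: logP > 2 and basic pKa in [6.5, 11].

    ``pka`` is the predicted pKa of the most basic center, supplied
    externally; when missing, the call is unknown (None).
    """
    if pka is None or (isinstance(pka, float) and pd.isna(pka)):
        return None
    return bool(logp > 2 and 6.5 <= pka <= 11)


def flag_records(records: list[CompoundRecord],
                 physchem: pd.DataFrame | None = None) -> list[CompoundRecord]:
    """Attach PAINS and lysosomotropism flags to standardized records.

    ``physchem`` is an optional sidecar table indexed by identifier with
    ``logp`` and ``pka`` columns (predicted values); without it the
    lysosomotropism call falls back to the computed logP and an unknown pKa.
    """
    for r in records:
        mol = r.standardized or r.raw_structure
        r.pains = pains_flags(mol)
        logp = r.descriptors.get("logP")
        pka = None
        if physchem is not None and r.identifier in physchem.index:
            row = physchem.loc[r.identifier]
            logp = float(row.get("logp", logp))
            pka = row.get("pka")
            pka = float(pka) if pd.notna(pka) else None
        r.lysosomotropic_like = (lysosomotropic_like(logp, pka)
                                 if logp is not None else None)
    return records


def records_to_frame(records: list[CompoundRecord]) -> pd.DataFrame:
    """Flat summary table of records (identifier, key, descriptors, flags)."""
    rows = []
    for r in records:
        row = {"identifier": r.identifier, "inchikey": r.inchikey,
               "available_mg": r.available_mg,
               "smiles": Chem.MolToSmiles(r.standardized)
               if r.standardized is not None else None}
        row.update(r.descriptors)
        row["pains"] = ";".join(r.pains) if r.pains else ""
        row["lysosomotropic_like"] = r.lysosomotropic_like
        rows.append(row)
    return pd.DataFrame(rows)
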
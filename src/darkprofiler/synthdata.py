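"""Synthetic plates, profiles, and toy structure files with known ground truth.

The generator emulates the data model of a Cell Painting screen: 384-well
plates with interspersed DMSO control wells, per-feature baseline levels and
dispersions drawn log-uniformly (so features are scale-heterogeneous, as
CellProfiler features are), cluster effect templates added to test compounds,
independent Gaussian (optionally heavy-tailed t, df=3) well noise, 9 sites
jittering around each well mean, and replicate runs with a tunable shared
noise component plus a "precipitation" failure mode that zeroes a compound's
effect in the second replicate.

Units: a cluster template is a sign pattern in {-1, 0, +1} over features;
``effect_size`` shifts each affected feature by that many per-feature
dispersion units, and ``noise_sd`` scales the well noise in the same units.
Because Z-scoring uses the raw control MAD, pure-noise Z-scores have
standard deviation 1/0.6745 = 1.4826 and an effect of size ``e`` lands at
about 1.4826 * e / noise_sd in Z units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CONTROL, TEST

PLATE_ROWS = "ABCDEFGHIJKLMNOP"


def plate_wells(n_wells: int) -> list[str]:
    """First ``n_wells`` well names in row-major 384-plate order."""
    if n_wells > 384:
        raise ValueError("a plate holds at most 384 wells")
    names = [f"{r}{c:02d}" for r in PLATE_ROWS for c in range(1, 25)]
    return names[:n_wells]


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic screen generator (seed is mandatory)."""

    seed: int
    n_features: int = 579
    n_wells_per_plate: int = 384
    n_sites: int = 9
    control_fraction: float = 0.125
    n_clusters: int = 13
    template_support: float = 0.15
    cluster_templates: dict[str, np.ndarray] | None = None
    effect_size: float = 4.0
    noise_sd: float = 1.0
    site_noise_sd: float = 0.5
    precipitation_rate: float = 0.0
    replicate_correlation: float = 0.0
    noise: str = "gaussian"  # or "t" (Student t, df=3)
    concentration_um: float = 10.0
    dmso_percent: float = 0.1

    def __post_init__(self):
        for name in ("control_fraction", "template_support",
                     "precipitation_rate", "replicate_correlation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise not in ("gaussian", "t"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.cluster_templates is not None:
            for name, t in self.cluster_templates.items():
                if len(t) != self.n_features:
                    raise ValueError(
                        f"template {name!r} has dimension {len(t)}, "
                        f"expected {self.n_features}")

    def feature_names(self) -> list[str]:
        return [f"f{i:04d}" for i in range(self.n_features)]


def make_cluster_templates(n_clusters: int, n_features: int,
                           support: float = 0.15,
                           seed: int = 0) -> dict[str, np.ndarray]:
    """Random sign-pattern effect templates, one per cluster.

    Each template is +-1 on a random ``support`` fraction of the features and
    0 elsewhere (unit max-norm).
    """
    rng = np.random.default_rng(seed)
    k = max(1, round(support * n_features))
    out = {}
    for i in range(n_clusters):
        t = np.zeros(n_features)
        idx = rng.choice(n_features, size=k, replace=False)
        t[idx] = rng.choice([-1.0, 1.0], size=k)
        out[f"cluster_{i + 1:02d}"] = t
    return out


@dataclass
class _RunSkeleton:
    """Shared structure of one or more replicate runs."""

    layout: pd.DataFrame          # one row per well, metadata only
    effects: np.ndarray           # (n_wells, n_features) shift in scale units
    medians: np.ndarray           # per-feature baseline median
    scales: np.ndarray            # per-feature dispersion scale
    templates: dict[str, np.ndarray]
    truth: pd.DataFrame = field(default=None)


def _build_skeleton(spec: GeneratorSpec, assignments, rng) -> _RunSkeleton:
    templates = spec.cluster_templates
    if templates is None:
        templates = make_cluster_templates(
            spec.n_clusters, spec.n_features, spec.template_support,
            seed=int(rng.integers(2**31)))
    medians = 10.0 ** rng.uniform(1.0, 3.0, size=spec.n_features)
    scales = 10.0 ** rng.uniform(-1.0, 1.0, size=spec.n_features)

    n_controls = max(3, round(spec.control_fraction * spec.n_wells_per_plate))
    n_test_per_plate = spec.n_wells_per_plate - n_controls

    if assignments is None:
        compounds = [f"cpd_{i + 1:04d}" for i in range(n_test_per_plate)]
        names = list(templates)
        assignments = {c: (names[i % len(names)] if i % 2 == 0 else None)
                       for i, c in enumerate(compounds)}
    else:
        unknown = {c for c in assignments.values()
                   if c is not None and c not in templates}
        if unknown:
            raise ValueError(f"assignments reference unknown clusters: "
                             f"{sorted(unknown)}")
        compounds = list(assignments)

    n_plates = -(-len(compounds) // n_test_per_plate)
    wells = plate_wells(spec.n_wells_per_plate)
    ctrl_pos = set(np.linspace(0, spec.n_wells_per_plate - 1, n_controls,
                               dtype=int).tolist())

    rows = []
    effect_rows = []
    truth_rows = []
    it = iter(compounds)
    for p in range(n_plates):
        plate = f"P{p + 1:03d}"
        for w_idx, well in enumerate(wells):
            if w_idx in ctrl_pos:
                rows.append((plate, well, "DMSO", 0.0, CONTROL,
                             spec.dmso_percent))
                effect_rows.append(np.zeros(spec.n_features))
            else:
                cid = next(it, None)
                if cid is None:
                    continue  # keep the plate's remaining control wells
                cluster = assignments[cid]
                rows.append((plate, well, cid, spec.concentration_um, TEST,
                             spec.dmso_percent))
                eff = (spec.effect_size * templates[cluster]
                       if cluster is not None else np.zeros(spec.n_features))
                effect_rows.append(eff)
                truth_rows.append({"compound_id": cid, "cluster": cluster,
                                   "effect_size": spec.effect_size
                                   if cluster is not None else 0.0,
                                   "precipitated": False,
                                   "plate_id": plate, "well": well})

    layout = pd.DataFrame(rows, columns=["plate_id", "well", "compound_id",
                                         "concentration_um", "role",
                                         "dmso_percent"])
    truth = pd.DataFrame(truth_rows)
    return _RunSkeleton(layout, np.vstack(effect_rows), medians, scales,
                        templates, truth)


def _noise(rng, spec: GeneratorSpec, shape) -> np.ndarray:
    if spec.noise == "t":
        return rng.standard_t(3, size=shape)
    return rng.standard_normal(size=shape)


def _materialize(skel: _RunSkeleton, spec: GeneratorSpec, rng,
                 shared_eps: np.ndarray | None = None,
                 effects: np.ndarray | None = None,
                 site_level: bool = True) -> pd.DataFrame:
    if effects is None:
        effects = skel.effects
    n_wells = len(skel.layout)
    eps = _noise(rng, spec, (n_wells, spec.n_features))
    rho = spec.replicate_correlation
    if shared_eps is not None and rho > 0:
        eps = np.sqrt(rho) * shared_eps + np.sqrt(1.0 - rho) * eps
    well_values = (skel.medians
                   + skel.scales * (effects + spec.noise_sd * eps))

    features = spec.feature_names()
    if not site_level:
        return pd.concat(
            [skel.layout.reset_index(drop=True),
             pd.DataFrame(well_values, columns=features)], axis=1)

    n_sites = spec.n_sites
    site_eps = _noise(rng, spec, (n_wells * n_sites, spec.n_features))
    values = (np.repeat(well_values, n_sites, axis=0)
              + skel.scales * spec.site_noise_sd * site_eps)
    meta = skel.layout.loc[skel.layout.index.repeat(n_sites)].reset_index(drop=True)
    meta.insert(2, "site", np.tile(np.arange(1, n_sites + 1), n_wells))
    return pd.concat([meta, pd.DataFrame(values, columns=features)], axis=1)


def generate_run(
    spec: GeneratorSpec,
    assignments: dict[str, str | None] | None = None,
    site_level: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One synthetic screening run.

    ``assignments`` maps compound_id -> cluster name (or None for an inactive
    compound); by default every other test well gets a cluster, round-robin.
    Returns the feature table (site-level unless ``site_level=False``) and the
    ground-truth table (compound, cluster, effect, precipitation status,
    position).  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    skel = _build_skeleton(spec, assignments, rng)
    table = _materialize(skel, spec, rng, site_level=site_level)
    return table, skel.truth


def generate_replicate_pair(
    spec: GeneratorSpec,
    assignments: dict[str, str | None] | None = None,
    site_level: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two replicate runs sharing layout, templates, and ground truth.

    A ``precipitation_rate`` fraction of the cluster-assigned (active)
    compounds is flagged as precipitated; their effect is zeroed in run 2,
    emulating compounds that drop out of solution after a freeze-thaw cycle.
    ``replicate_correlation`` adds a shared well-noise component to both runs.
    Returns (run1, run2, truth).
    """
    rng = np.random.default_rng(spec.seed)
    skel = _build_skeleton(spec, assignments, rng)

    active = skel.truth["cluster"].notna().to_numpy()
    precip = np.zeros(len(skel.truth), dtype=bool)
    precip[active] = rng.random(int(active.sum())) < spec.precipitation_rate
    skel.truth["precipitated"] = precip

    effects2 = skel.effects.copy()
    test_mask = (skel.layout["role"] == TEST).to_numpy()
    test_idx = np.nonzero(test_mask)[0]
    effects2[test_idx[precip]] = 0.0

    shared = (_noise(rng, spec, skel.effects.shape)
              if spec.replicate_correlation > 0 else None)
    run1 = _materialize(skel, spec, rng, shared_eps=shared,
                        site_level=site_level)
    run2 = _materialize(skel, spec, rng, shared_eps=shared,
                        effects=effects2, site_level=site_level)
    return run1, run2, skel.truth


def generate_reference_plate_pair(
    n_signal: int = 10,
    n_noise: int = 10,
    n_wells: int = 96,
    signal_r: float = 0.95,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Two repeats of a reference plate for robust-feature selection tests.

    ``n_signal`` features carry a shared per-well signal so their cross-repeat
    correlation is ~``signal_r``; ``n_noise`` features are independent noise
    (correlation ~0).  Returns (repeat_a, repeat_b, signal feature names).
    """
    rng = np.random.default_rng(seed)
    wells = plate_wells(n_wells)

    def tables():
        shared = rng.standard_normal((n_wells, n_signal))
        a_sig = (np.sqrt(signal_r) * shared
                 + np.sqrt(1 - signal_r) * rng.standard_normal((n_wells, n_signal)))
        b_sig = (np.sqrt(signal_r) * shared
                 + np.sqrt(1 - signal_r) * rng.standard_normal((n_wells, n_signal)))
        a_noise = rng.standard_normal((n_wells, n_noise))
        b_noise = rng.standard_normal((n_wells, n_noise))
        return np.hstack([a_sig, a_noise]), np.hstack([b_sig, b_noise])

    A, B = tables()
    sig_names = [f"signal_{i + 1:02d}" for i in range(n_signal)]
    noise_names = [f"noise_{i + 1:02d}" for i in range(n_noise)]
    names = sig_names + noise_names

    def frame(M):
        meta = pd.DataFrame({
            "plate_id": "REF", "well": wells,
            "compound_id": [f"ref_{i + 1:03d}" for i in range(n_wells)],
            "concentration_um": 10.0, "role": TEST, "dmso_percent": 0.1,
        })
        return pd.concat([meta, pd.DataFrame(M, columns=names)], axis=1)

    return frame(A), frame(B), sig_names


# ---------------------------------------------------------------------------
# toy structure files
# ---------------------------------------------------------------------------

# Drug-like structures with >= 25 heavy atoms (checked at generation time).
_LARGE_SMILES = [
    "CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CCC(O)CC(O)CC(=O)O",
    "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
    "CN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc32)CC1CCO",
    "COc1ccc(CCN(C)CCCC(C#N)(c2ccc(OC)c(OC)c2)C(C)C)cc1OC",
    "O=C(Nc1ccc(N2CCOCC2)cc1)c1ccc(CN2CCN(C)CC2)cc1C(F)(F)F",
    "CCOC(=O)c1ccc(NC(=O)c2ccc(OCC(=O)N3CCCCC3)cc2)cc1OC",
    "CN(C)CCCN1c2ccccc2Sc2ccc(S(=O)(=O)N(C)C)cc21",
]

# Structures with < 25 heavy atoms.
_SMALL_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",       # aspirin, 13 heavy atoms
    "CC(=O)Nc1ccc(O)cc1",          # paracetamol, 11
    "c1ccc2[nH]ccc2c1",            # indole, 9
]

# Multi-fragment (salt) forms; largest fragment is the parent structure.
_SALT_SMILES = [
    "CN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc32)CC1CCO.Cl",
    "CC(=O)Oc1ccccc1C(=O)[O-].[Na+]",
]

_CORRUPT_MOLBLOCK = """corrupt_record
  synthetic

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
> <available>
5.0

$$$$
"""


def generate_toy_sdf(
    seed: int = 0,
    n_duplicate_pairs: int = 1,
    include_corrupt: bool = False,
) -> tuple[str, pd.DataFrame]:
    """A small V2000 SDF with salts, duplicates, and sub-25-heavy-atom records.

    Every record carries an ``available`` data field (amount in mg).  Returns
    the SDF text and a ground-truth table (identifier, category, smiles,
    available_mg, n_heavy).  Byte-for-byte reproducible for a given seed.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rng = np.random.default_rng(seed)
    entries = []  # (identifier, smiles, category)
    for i, smi in enumerate(_LARGE_SMILES):
        entries.append((f"LRG-{i + 1:03d}", smi, "large"))
    for i, smi in enumerate(_SMALL_SMILES):
        entries.append((f"SML-{i + 1:03d}", smi, "small"))
    for i, smi in enumerate(_SALT_SMILES):
        entries.append((f"SLT-{i + 1:03d}", smi, "salt"))
    for i in range(n_duplicate_pairs):
        entries.append((f"DUP-{i + 1:03d}", _LARGE_SMILES[i], "duplicate"))

    blocks = []
    truth = []
    for ident, smi, category in entries:
        mol = Chem.MolFromSmiles(smi)
        if category == "large":
            assert mol.GetNumHeavyAtoms() >= 25, smi
        if category == "small":
            assert mol.GetNumHeavyAtoms() < 25, smi
        AllChem.Compute2DCoords(mol)
        mol.SetProp("_Name", ident)
        available = float(np.round(rng.uniform(0.5, 20.0), 2))
        block = Chem.MolToMolBlock(mol, kekulize=True)
        blocks.append(f"{block}> <available>\n{available}\n\n$$$$\n")
        truth.append({"identifier": ident, "category": category,
                      "smiles": smi, "available_mg": available,
                      "n_heavy": Chem.MolFromSmiles(smi.split('.')[0]).GetNumHeavyAtoms()
                      if category != "salt" else None})
    if include_corrupt:
        blocks.append(_CORRUPT_MOLBLOCK)
        truth.append({"identifier": "corrupt_record", "category": "corrupt",
                      "smiles": None, "available_mg": 5.0, "n_heavy": None})
    return "".join(blocks), pd.DataFrame(truth)


def toy_funnel_records():
    """Eight compound records wired so the funnel reads 8 -> 6 -> 4 -> 3.

    Two records fail availability (one under 2 mg, one with a missing amount),
    two are under 25 heavy atoms, and one overlaps the returned reference key
    set.  Returns (records, reference_keys, expected_counts).
    """
    from rdkit import Chem

    from .curation import CompoundRecord, standardize_and_key

    layout = [
        ("BIG-KEEP-1", _LARGE_SMILES[0], 10.0),
        ("BIG-KEEP-2", _LARGE_SMILES[1], 10.0),
        ("BIG-KEEP-3", _LARGE_SMILES[2], 10.0),
        ("BIG-OVERLAP", _LARGE_SMILES[3], 10.0),
        ("BIG-LOWAMT", _LARGE_SMILES[4], 1.0),
        ("BIG-NOAMT", _LARGE_SMILES[5], None),
        ("SMALL-1", _SMALL_SMILES[0], 10.0),
        ("SMALL-2", _SMALL_SMILES[1], 10.0),
    ]
    records = [CompoundRecord(ident, Chem.MolFromSmiles(smi), avail)
               for ident, smi, avail in layout]
    standardize_and_key(records)
    reference_keys = {r.inchikey for r in records
                      if r.identifier == "BIG-OVERLAP"}
    expected = {"input": 8, "availability": 6, "size": 4, "overlap": 3}
    return records, reference_keys, expected


def replicate_spec(spec: GeneratorSpec, **changes) -> GeneratorSpec:
    """Copy of a spec with fields replaced (templates shared by reference)."""
    return dataclasses.replace(spec, **changes)
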
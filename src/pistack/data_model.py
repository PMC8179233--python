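"""Dataset assembly: SMILES parsing, molecule/pair filtering, pair enumeration.

Molecules are carried as :class:`MoleculeRecord` and unordered pairs as
:class:`PairRecord`.  Multi-component entries use the dotted SMILES convention
(components separated by a full stop); duplicate components are merged with
multiplicity so that stoichiometry is preserved.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: default SMARTS patterns for acidic hydrogens (carboxylic O-H, phenol O-H,
#: N-H donors).  Editable through :class:`FilterConfig`.
DEFAULT_ACIDIC_H_SMARTS: tuple[str, ...] = (
    "[CX3](=O)[OX2H1]",  # carboxylic acid
    "[c,C][OX2H1]",      # phenol / alcohol O-H
    "[NX3;H1,H2]",       # primary / secondary amine or amide N-H
    "[SX2H1]",           # thiol
)

#: default common non-aromatic solvents, by SMILES.  Editable resource.
DEFAULT_NONAROMATIC_SOLVENTS: tuple[str, ...] = (
    "O",            # water
    "CO",           # methanol
    "CCO",          # ethanol
    "CC(C)=O",      # acetone
    "C1CCOC1",      # THF
    "ClCCl",        # dichloromethane
    "ClC(Cl)Cl",    # chloroform
    "CC#N",         # acetonitrile
    "CCOCC",        # diethyl ether
    "CCCCCC",       # hexane
    "CS(C)=O",      # DMSO
    "CN(C)C=O",     # DMF
)


class ParseError(ValueError):
    """An input SMILES string could not be parsed."""


class ConfigError(ValueError):
    """A filter configuration entry is invalid (e.g. a SMARTS that fails to compile)."""


class ReferentialError(KeyError):
    """A pair references a molecule id that is not in the molecule table."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule with its numeric representation.

    Parameters
    ----------
    mol_id
        Opaque identifier, unique within a dataset.
    smiles
        Canonical SMILES of a single connected component.
    descriptors
        Backend-defined fixed-length numeric vector, or ``None`` before
        featurization.
    fingerprint
        Fixed-length bit vector used for Tanimoto similarity, or ``None``.
    """

    mol_id: str
    smiles: str
    descriptors: np.ndarray | None = None
    fingerprint: np.ndarray | None = None
    is_aromatic_solvent: bool = False
    source: str = "labelled"  # {"labelled", "candidate"}


@dataclass(frozen=True)
class PairRecord:
    """Unordered pair of molecule ids with label provenance and stoichiometry."""

    mol_a: str
    mol_b: str
    label: str = "candidate"  # {"known_cocrystal", "candidate"}
    counts: Mapping[str, int] | None = None
    source_refcode: str | None = None

    def __post_init__(self) -> None:
        # unordered identity: store endpoints in sorted order
        if self.mol_b < self.mol_a:
            a, b = self.mol_a, self.mol_b
            object.__setattr__(self, "mol_a", b)
            object.__setattr__(self, "mol_b", a)
        if self.counts is not None:
            extra = set(self.counts) - {self.mol_a, self.mol_b}
            if extra:
                raise ValueError(f"counts reference unknown molecules: {sorted(extra)}")

    @property
    def pair_id(self) -> str:
        return f"{self.mol_a}|{self.mol_b}"


@dataclass
class FilterConfig:
    """Configuration of the dataset filters."""

    acidic_h_smarts: Sequence[str] = DEFAULT_ACIDIC_H_SMARTS
    nonaromatic_solvent_smiles: Sequence[str] = DEFAULT_NONAROMATIC_SOLVENTS
    tanimoto_threshold: float = 0.35
    _acidic_patterns: list = field(init=False, repr=False, default_factory=list)
    _solvent_canonical: set = field(init=False, repr=False, default_factory=set)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tanimoto_threshold <= 1.0:
            raise ConfigError(f"tanimoto_threshold must be in [0,1], got {self.tanimoto_threshold}")
        for smarts in self.acidic_h_smarts:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ConfigError(f"invalid SMARTS pattern: {smarts!r}")
            self._acidic_patterns.append(patt)
        for smi in self.nonaromatic_solvent_smiles:
            self._solvent_canonical.add(canonical_smiles(smi))


def canonical_smiles(smiles: str) -> str:
    """Return the canonical form of a single-component SMILES.

    Raises
    ------
    ParseError
        If RDKit cannot parse the string.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES component: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class ParsedEntry:
    """Result of parsing one multi-component SMILES entry."""

    components: tuple[str, ...]       # distinct canonical components, first-seen order
    counts: Mapping[str, int]         # canonical SMILES -> multiplicity
    ratio: str                        # "1:1" or "other"
    is_pair: bool                     # exactly two distinct components

    def serialize(self) -> str:
        """Dotted SMILES with multiplicities expanded (round-trips the multiset)."""
        return ".".join(
            itertools.chain.from_iterable([c] * self.counts[c] for c in self.components)
        )


def parse_multicomponent_smiles(entry: str) -> ParsedEntry:
    """Parse a dotted multi-component SMILES entry.

    Components are canonicalized and identical components merged with
    multiplicity.  The ratio classification is ``"1:1"`` iff there are exactly
    two distinct components, each with count 1; entries with a number of
    distinct components other than two are flagged ``is_pair=False`` and are
    excluded from the pair dataset downstream.
    """
    if not entry or not entry.strip():
        raise ValueError("empty multi-component SMILES entry")
    counts: Counter[str] = Counter()
    order: list[str] = []
    for raw in entry.strip().split("."):
        can = canonical_smiles(raw)
        if can not in counts:
            order.append(can)
        counts[can] += 1
    is_pair = len(order) == 2
    ratio = "1:1" if is_pair and all(counts[c] == 1 for c in order) else "other"
    return ParsedEntry(components=tuple(order), counts=dict(counts), ratio=ratio, is_pair=is_pair)


def compute_fingerprint(smiles: str, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Morgan (ECFP-like) fingerprint as a uint8 0/1 vector.

    The fingerprint backend is pluggable by contract; this default is a
    circular fingerprint, chosen because the database-native fingerprint the
    workflow originally relied on is proprietary.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two bit vectors (0.0 if both empty)."""
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def filter_acidic_hydrogens(
    molecules: Sequence[MoleculeRecord], cfg: FilterConfig
) -> list[MoleculeRecord]:
    """Drop molecules matching any configured acidic-hydrogen SMARTS pattern.

    Input order of the retained molecules is preserved; the filter is
    idempotent.
    """
    kept = []
    for rec in molecules:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise ParseError(f"unparsable SMILES for {rec.mol_id}: {rec.smiles!r}")
        if not any(mol.HasSubstructMatch(p) for p in cfg._acidic_patterns):
            kept.append(rec)
    return kept


def is_benzene_like(smiles: str) -> bool:
    """Heuristic for "benzene-like" aromatic solvents.

    A molecule with exactly one ring, fully aromatic, and at most one
    heavy atom outside the ring (benzene, toluene, ...).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    ri = mol.GetRingInfo()
    if ri.NumRings() != 1:
        return False
    ring_atoms = set(ri.AtomRings()[0])
    if not all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring_atoms):
        return False
    n_outside = mol.GetNumHeavyAtoms() - len(ring_atoms)
    return n_outside <= 1


def filter_solvent_pairs(
    pairs: Sequence[PairRecord],
    molecules: Mapping[str, MoleculeRecord] | Sequence[MoleculeRecord],
    cfg: FilterConfig,
) -> list[PairRecord]:
    """Drop pairs containing a molecule on the non-aromatic solvent list.

    Aromatic solvents (e.g. benzene) are *kept* -- their interactions are the
    stacking interactions this class of co-crystals is defined by.
    """
    table = _as_table(molecules)
    kept = []
    for pair in pairs:
        for mid in (pair.mol_a, pair.mol_b):
            if mid not in table:
                raise ReferentialError(f"pair {pair.pair_id} references unknown molecule {mid!r}")
        smi_a = canonical_smiles(table[pair.mol_a].smiles)
        smi_b = canonical_smiles(table[pair.mol_b].smiles)
        if smi_a in cfg._solvent_canonical or smi_b in cfg._solvent_canonical:
            continue
        kept.append(pair)
    return kept


def similarity_search(
    queries: Sequence[MoleculeRecord],
    database: Sequence[MoleculeRecord],
    cfg: FilterConfig,
) -> list[MoleculeRecord]:
    """Return database molecules with Tanimoto similarity > threshold to any query.

    Results are deduplicated by ``mol_id`` and returned in database order.
    Strict inequality, matching the ">0.35" screening rule.
    """
    if not queries:
        return []
    qfps = [_require_fp(q) for q in queries]
    length = qfps[0].shape[0]
    for fp in qfps:
        if fp.shape[0] != length:
            raise ValueError("query fingerprints have mismatched lengths")
    hits: list[MoleculeRecord] = []
    seen: set[str] = set()
    for rec in database:
        fp = _require_fp(rec)
        if fp.shape[0] != length:
            raise ValueError(
                f"fingerprint length mismatch for {rec.mol_id}: {fp.shape[0]} != {length}"
            )
        if rec.mol_id in seen:
            continue
        if any(tanimoto(fp, q) > cfg.tanimoto_threshold for q in qfps):
            hits.append(rec)
            seen.add(rec.mol_id)
    return hits


def enumerate_candidate_pairs(molecules: Sequence[MoleculeRecord]) -> list[PairRecord]:
    """All n(n-1)/2 unordered pairs of distinct molecules, label ``candidate``.

    Self-pairs are excluded; 209 molecules yield 21 736 pairs.
    """
    ids = [m.mol_id for m in molecules]
    if len(set(ids)) != len(ids):
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        raise ValueError(f"duplicate mol_ids: {dupes}")
    return [
        PairRecord(mol_a=a, mol_b=b, label="candidate")
        for a, b in itertools.combinations(sorted(ids), 2)
    ]


def dedupe_pairs(entries: Iterable[ParsedEntry]) -> list[ParsedEntry]:
    """Deduplicate parsed entries by canonical component multiset."""
    seen: set[tuple[tuple[str, int], ...]] = set()
    out = []
    for entry in entries:
        key = tuple(sorted(entry.counts.items()))
        if key not in seen:
            seen.add(key)
            out.append(entry)
    return out


def annotate_aromatic_solvents(molecules: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Set ``is_aromatic_solvent`` from the benzene-like heuristic."""
    return [replace(m, is_aromatic_solvent=is_benzene_like(m.smiles)) for m in molecules]


def _require_fp(rec: MoleculeRecord) -> np.ndarray:
    if rec.fingerprint is None:
        raise ValueError(f"molecule {rec.mol_id} has no fingerprint")
    return np.asarray(rec.fingerprint)


def _as_table(
    molecules: Mapping[str, MoleculeRecord] | Sequence[MoleculeRecord],
) -> Mapping[str, MoleculeRecord]:
    if isinstance(molecules, Mapping):
        return molecules
    return {m.mol_id: m for m in molecules}
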
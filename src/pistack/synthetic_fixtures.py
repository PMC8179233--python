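"""Seeded generators with the statistical structure the workflow assumes.

The generators are pure functions of the seed.  Molecules get a descriptor
matrix with planted structure for the engineering steps (an inter-correlated
block for the 0.92 pruning, constant columns for the variance filter,
independent columns) plus a set of "key" complementarity features driven by a
per-molecule latent size factor.  Labelled inlier pairs are drawn through a
Gaussian copula over that factor, so the key features are pairwise correlated
across co-formers at a configurable strength; planted outlier pairs are paired
at random (no cross-co-former correlation).  Stoichiometry labels follow a
configurable dominant 1:1 share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import MoleculeRecord, PairRecord

_SMILES_POOL = (
    "c1ccccc1",                 # benzene
    "Cc1ccccc1",                # toluene
    "c1ccc2ccccc2c1",           # naphthalene
    "c1ccc2cc3ccccc3cc2c1",     # anthracene
    "c1cc2ccc3cccc4ccc(c1)c2c34",  # pyrene
    "c1ccc2c(c1)ccc1ccccc12",   # phenanthrene
    "N#Cc1ccccc1",              # benzonitrile
    "c1ccc(-c2ccccc2)cc1",      # biphenyl
)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and strength of the planted structure; deterministic per seed."""

    n_molecules: int = 200
    n_descriptors: int = 30
    n_complementary: int = 6
    n_corr_block: int = 4
    n_constant: int = 2
    n_labelled_pairs: int = 300
    outlier_fraction: float = 0.0
    correlation: float = 0.8
    ratio_one_one_share: float = 0.8
    key_noise: float = 0.4
    low_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_complementary + self.n_corr_block + self.n_constant
        if planted > self.n_descriptors:
            raise ValueError(
                f"planted columns ({planted}) exceed n_descriptors ({self.n_descriptors})"
            )
        for name in ("n_molecules", "n_descriptors", "n_labelled_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("outlier_fraction", "correlation", "ratio_one_one_share"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")

    @property
    def key_indices(self) -> list[int]:
        return list(range(self.n_complementary))

    @property
    def block_indices(self) -> list[int]:
        return list(range(self.n_complementary, self.n_complementary + self.n_corr_block))

    @property
    def constant_indices(self) -> list[int]:
        start = self.n_complementary + self.n_corr_block
        return list(range(start, start + self.n_constant))


@dataclass
class MoleculeFixture:
    molecules: list[MoleculeRecord]
    descriptors: pd.DataFrame  # molecules x descriptors, index = mol_id
    factor: pd.Series          # hidden latent size factor per molecule
    spec: FixtureSpec = field(repr=False, default=None)


@dataclass
class PairFixture:
    pairs: list[PairRecord]
    ground_truth: pd.DataFrame  # pair_id, mol_a, mol_b, is_outlier, ratio_label


def generate_molecules(spec: FixtureSpec) -> MoleculeFixture:
    """Molecule table + descriptor matrix with the planted column structure.

    Column layout (deterministic): ``[key | correlated block | constants |
    independent]``.  Key columns are ``factor * scale_j + shift_j`` with a
    small noise term, so any pairing rule applied to the factor shows up as a
    cross-co-former correlation on every key column.  Block columns share one
    base signal (pairwise r ~ 0.998 > 0.92); constants have zero variance;
    scale factors keep all non-constant variances >= 1 (> the 0.4 default).
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_molecules, spec.n_descriptors
    factor = rng.normal(size=n)
    X = np.empty((n, d))
    for j in spec.key_indices:
        scale = rng.uniform(1.0, 2.0)
        shift = rng.uniform(-3.0, 3.0)
        X[:, j] = (factor + spec.key_noise * rng.normal(size=n)) * scale + shift
    base = rng.normal(size=n)
    for j in spec.block_indices:
        X[:, j] = (base + 0.05 * rng.normal(size=n)) * rng.uniform(1.0, 2.0)
    for j in spec.constant_indices:
        X[:, j] = rng.uniform(-5.0, 5.0)
    n_planted = spec.n_complementary + spec.n_corr_block + spec.n_constant
    for j in range(n_planted, d):
        X[:, j] = rng.normal(size=n) * rng.uniform(1.0, 2.0)
    mol_ids = [f"M{i:04d}" for i in range(n)]
    molecules = [
        MoleculeRecord(
            mol_id=mid,
            smiles=_SMILES_POOL[i % len(_SMILES_POOL)],
            descriptors=X[i].copy(),
            source="labelled",
        )
        for i, mid in enumerate(mol_ids)
    ]
    descriptors = pd.DataFrame(
        X, index=mol_ids, columns=[f"d{j:03d}" for j in range(d)]
    )
    return MoleculeFixture(
        molecules=molecules,
        descriptors=descriptors,
        factor=pd.Series(factor, index=mol_ids, name="factor"),
        spec=spec,
    )


def generate_labelled_pairs(spec: FixtureSpec, fixture: MoleculeFixture) -> PairFixture:
    """Labelled pairs with planted inlier/outlier structure and ratio labels.

    Inlier pairs: a latent bivariate-normal draw with the configured
    correlation is mapped through the empirical factor distribution (Gaussian
    copula) to pick the two member molecules, so key features end up pairwise
    correlated across co-formers at ~ the configured strength.  Outlier
    pairs: uniform random distinct molecules (no cross correlation).  Ratio
    counts are {1,1} with the configured share, else {1,2}.
    """
    if spec.n_molecules < 4:
        raise ValueError("need at least 4 molecules to draw distinct pairs")
    rng = np.random.default_rng(spec.seed + 1)
    factor = fixture.factor.to_numpy()
    order = np.argsort(factor)
    mol_ids = list(fixture.factor.index)
    n_pairs = spec.n_labelled_pairs
    n_out = int(round(spec.outlier_fraction * n_pairs))
    # compensate the key-noise attenuation: corr(keyA, keyB) = rho_f / (1 + s^2)
    rho = float(np.clip(spec.correlation * (1.0 + spec.key_noise**2), 0.0, 1.0))
    cov = np.array([[1.0, rho], [rho, 1.0]])
    records: list[PairRecord] = []
    rows = []
    for i in range(n_pairs):
        is_outlier = i >= n_pairs - n_out
        if is_outlier:
            ia, ib = rng.choice(spec.n_molecules, size=2, replace=False)
        else:
            z = rng.multivariate_normal(np.zeros(2), cov)
            # Gaussian copula over factor ranks; low_bias > 1 skews inlier
            # pairs toward the low-factor regime (marginal + joint signal)
            u = norm.cdf(z) ** spec.low_bias
            ia = order[min(int(u[0] * spec.n_molecules), spec.n_molecules - 1)]
            ib = order[min(int(u[1] * spec.n_molecules), spec.n_molecules - 1)]
            if ib == ia:
                ib = order[(np.where(order == ia)[0][0] + 1) % spec.n_molecules]
        a, b = mol_ids[ia], mol_ids[ib]
        one_one = rng.uniform() < spec.ratio_one_one_share
        counts = {a: 1, b: 1} if one_one else ({a: 1, b: 2} if a < b else {a: 2, b: 1})
        rec = PairRecord(
            mol_a=a, mol_b=b, label="known_cocrystal", counts=counts,
            source_refcode=f"FIX{i:05d}",
        )
        records.append(rec)
        rows.append(
            {
                "pair_id": rec.pair_id,
                "mol_a": rec.mol_a,
                "mol_b": rec.mol_b,
                "first_member": a,
                "second_member": b,
                "is_outlier": is_outlier,
                "ratio_label": 0 if one_one else 1,
            }
        )
    return PairFixture(pairs=records, ground_truth=pd.DataFrame(rows))



def pair_value_arrays(
    fixture: MoleculeFixture, pair_fixture: PairFixture, columns=None
) -> tuple[np.ndarray, np.ndarray]:
    """(A, B) descriptor value arrays over pairs, in generated member order."""
    desc = fixture.descriptors if columns is None else fixture.descriptors[columns]
    gt = pair_fixture.ground_truth
    A = desc.loc[gt["first_member"]].to_numpy(dtype=float)
    B = desc.loc[gt["second_member"]].to_numpy(dtype=float)
    return A, B
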
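"""Encoder-decoder contract between chemical space and the continuous latent space.

A codec maps molecules (SMILES strings) to fixed-dimension real vectors and
back. Production use plugs in a pretrained generative codec (e.g. a
translation-model embedding of dimension 512); the package ships two
deterministic mocks so the full optimization loop is testable without
pretrained weights:

* ``TableCodec`` — a finite molecule world with exact-lookup encoding and
  nearest-neighbour decoding.
* ``IdentityCodec`` — a transparent codec whose "molecules" are formatted
  coordinate strings, used by analytic test problems with known fronts.

``decode`` may fail (return ``None``): real decoders occasionally emit
invalid strings, and the pipeline filters these out rather than erroring.
"""

from __future__ import annotations

from typing import Callable, Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from .chem import CanonicalMolecule, parse_smiles
from .errors import DimensionMismatch, InvalidSmiles, UnknownMolecule


@runtime_checkable
class Codec(Protocol):
    """Plug-in codec contract: ``dim``, ``encode``, ``decode``, optional ``bounds``."""

    dim: int
    # bounds: None or (lo, hi) arrays of length dim; offspring are clamped
    # to declared bounds after variation.
    bounds: Optional[tuple[np.ndarray, np.ndarray]]

    def encode(self, smiles: str) -> np.ndarray: ...

    def decode(self, z: np.ndarray) -> Optional[str]: ...


def _check_dim(codec, z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.shape != (codec.dim,):
        raise DimensionMismatch(
            f"latent vector of shape {z.shape}, codec dimension {codec.dim}"
        )
    return z


def clamp(z: np.ndarray, bounds: Optional[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Clamp a latent vector to per-dimension bounds (no-op if none declared)."""
    if bounds is None:
        return z
    lo, hi = bounds
    return np.clip(z, lo, hi)


class TableCodec:
    """A finite deterministic codec over an explicit (SMILES, vector) table.

    Encoding is exact lookup by canonical SMILES; decoding returns the
    nearest entry under Euclidean distance, ties broken by lowest entry
    index. Round-trips are exact on every entry. Bounds default to the unit
    hypercube.
    """

    def __init__(
        self,
        entries: Sequence[tuple[str, np.ndarray]],
        bounds: Optional[tuple[np.ndarray, np.ndarray]] = "unit",
    ):
        if not entries:
            raise ValueError("TableCodec requires at least one entry")
        smiles, vecs = zip(*entries)
        self._vectors = np.asarray(vecs, dtype=float)
        if self._vectors.ndim != 2:
            raise DimensionMismatch("entry vectors must share one fixed dimension")
        self.dim = int(self._vectors.shape[1])
        self.smiles: list[str] = []
        self._index: dict[str, int] = {}
        for i, s in enumerate(smiles):
            canon = parse_smiles(s).smiles
            if canon in self._index:
                raise ValueError(f"duplicate table entry {canon!r}")
            self._index[canon] = i
            self.smiles.append(canon)
        if len({tuple(v) for v in self._vectors}) != len(self._vectors):
            raise ValueError("table entries must have distinct vectors")
        if isinstance(bounds, str) and bounds == "unit":
            bounds = (np.zeros(self.dim), np.ones(self.dim))
        self.bounds = bounds

    def __len__(self) -> int:
        return len(self.smiles)

    def encode(self, smiles: str) -> np.ndarray:
        canon = parse_smiles(smiles).smiles
        try:
            return self._vectors[self._index[canon]].copy()
        except KeyError:
            raise UnknownMolecule(f"molecule not in codec table: {canon!r}") from None

    def decode(self, z: np.ndarray) -> Optional[str]:
        z = _check_dim(self, z)
        d2 = ((self._vectors - z) ** 2).sum(axis=1)
        return self.smiles[int(np.argmin(d2))]  # argmin takes the lowest index on ties

    # -- CSV serialization: columns smiles, z_0..z_{D-1} --------------------

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self._vectors, columns=[f"z_{i}" for i in range(self.dim)])
        df.insert(0, "smiles", self.smiles)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TableCodec":
        import pandas as pd

        df = pd.read_csv(path)
        zcols = [c for c in df.columns if c.startswith("z_")]
        zcols.sort(key=lambda c: int(c.split("_")[1]))
        entries = [
            (row["smiles"], np.asarray([row[c] for c in zcols], dtype=float))
            for _, row in df.iterrows()
        ]
        return cls(entries)


class IdentityCodec:
    """Transparent codec for analytic test problems.

    A "molecule" is the string rendering of its own latent coordinates
    (full ``repr`` precision, comma-separated), so encode/decode are exact
    inverses and no chemistry is involved.
    """

    def __init__(self, dim: int = 2):
        self.dim = int(dim)
        self.bounds = (np.zeros(self.dim), np.ones(self.dim))

    @staticmethod
    def token(z: np.ndarray) -> str:
        return ",".join(repr(float(v)) for v in z)

    @staticmethod
    def coords(token: str) -> np.ndarray:
        return np.array([float(p) for p in token.split(",")], dtype=float)

    def encode(self, smiles: str) -> np.ndarray:
        z = self.coords(smiles)
        if z.shape != (self.dim,):
            raise DimensionMismatch(f"token has {z.shape[0]} coords, dim {self.dim}")
        return z

    def decode(self, z: np.ndarray) -> Optional[str]:
        return self.token(_check_dim(self, z))


def identity_parse(token: str) -> CanonicalMolecule:
    """Parser for IdentityCodec tokens (the analytic problems' 'canonicalizer')."""
    if not token:
        raise ValueError("empty token")
    try:
        IdentityCodec.coords(token)
    except Exception as e:
        raise InvalidSmiles(f"bad coordinate token {token!r}") from e
    return CanonicalMolecule(smiles=token, mol=None)


def decode_valid_batch(
    codec: Codec,
    zs: Sequence[np.ndarray],
    parse: Callable[[str], CanonicalMolecule] = parse_smiles,
    exclude: Optional[set[str]] = None,
) -> list[tuple[int, CanonicalMolecule, np.ndarray]]:
    """Decode a batch of latent vectors, keeping only valid, distinct molecules.

    Each vector is decoded; decode failures and unparsable strings are
    dropped; survivors are canonicalized; duplicates (within the batch, and
    against ``exclude`` canonical strings if given) are dropped keeping the
    first occurrence. Input order is preserved. Returns
    ``(input index, molecule, latent vector)`` triples.
    """
    seen: set[str] = set(exclude) if exclude else set()
    out: list[tuple[int, CanonicalMolecule, np.ndarray]] = []
    for i, z in enumerate(zs):
        z = _check_dim(codec, z)
        s = codec.decode(z)
        if s is None:
            continue
        try:
            m = parse(s)
        except (InvalidSmiles, ValueError):
            continue
        if m.smiles in seen:
            continue
        seen.add(m.smiles)
        out.append((i, m, z))
    return out
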
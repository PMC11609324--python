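"""Within- and between-network mean connectivity features.

A subject's parcel-by-parcel matrix of variance-stabilized correlations
(Fisher z = atanh r) is reduced to 10 features: the mean over unique
within-network parcel pairs for each of the four networks, and the mean over
all cross pairs for each of the six unordered network pairings. All
summaries operate on the z scale and ignore the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .netdef_atlas import BETWEEN_KEYS, FEATURE_KEYS, WITHIN_KEYS, NetworkParcelMap

SYMMETRY_TOL = 1e-8


class ConnectivityError(ValueError):
    pass


def variance_stabilize(r):
    """Fisher z transform, z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ConnectivityError("correlations must satisfy |r| < 1 for atanh")
    return np.arctanh(r)


def inverse_variance_stabilize(z):
    """Inverse of the Fisher z transform, r = tanh(z)."""
    return np.tanh(np.asarray(z, dtype=float))


@dataclass
class ConnectivityMatrix:
    """Symmetric P x P matrix of variance-stabilized correlations."""

    values: np.ndarray
    parcel_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=int)
        p = len(self.parcel_ids)
        if self.values.shape != (p, p):
            raise ConnectivityError(f"matrix shape {self.values.shape} != ({p}, {p})")
        if len(np.unique(self.parcel_ids)) != p:
            raise ConnectivityError("parcel ids must be unique")
        off = ~np.eye(p, dtype=bool)
        if not np.all(np.isfinite(self.values[off])):
            raise ConnectivityError("non-finite off-diagonal connectivity values")
        if np.max(np.abs(self.values - self.values.T)) > SYMMETRY_TOL:
            raise ConnectivityError(f"matrix asymmetric beyond {SYMMETRY_TOL}")

    def index_of(self, parcel_ids) -> np.ndarray:
        pos = {pid: i for i, pid in enumerate(self.parcel_ids)}
        try:
            return np.array([pos[p] for p in parcel_ids], dtype=int)
        except KeyError as e:
            raise ConnectivityError(f"parcel {e.args[0]} missing from matrix") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConnectivityMatrix":
        t = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=t.to_numpy(dtype=float), parcel_ids=t.columns.astype(int).to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.parcel_ids, columns=self.parcel_ids).to_csv(
            path, sep="\t"
        )


def within_network_mean(m: ConnectivityMatrix, pmap: NetworkParcelMap, net: str) -> float:
    """Mean z over the k(k-1)/2 unique parcel pairs of one network."""
    parcels = pmap.parcels_by_network().get(net, [])
    if len(parcels) < 2:
        raise ConnectivityError(f"network {net} has {len(parcels)} parcel(s); need >= 2")
    idx = m.index_of(parcels)
    sub = m.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def between_network_mean(m: ConnectivityMatrix, pmap: NetworkParcelMap, a: str, b: str) -> float:
    """Mean z over all k_a * k_b cross pairs of two distinct networks."""
    if a == b:
        raise ConnectivityError("between_network_mean requires two distinct networks")
    by_net = pmap.parcels_by_network()
    for net in (a, b):
        if not by_net.get(net):
            raise ConnectivityError(f"network {net} has no parcels in the map")
    ia, ib = m.index_of(by_net[a]), m.index_of(by_net[b])
    return float(m.values[np.ix_(ia, ib)].mean())


def extract_features(m: ConnectivityMatrix, pmap: NetworkParcelMap) -> dict[str, float]:
    """All 10 features, in the fixed key order ERN1..ERN4, ERN12..ERN34."""
    feats = {net: within_network_mean(m, pmap, net) for net in WITHIN_KEYS}
    for key in BETWEEN_KEYS:
        a, b = "ERN" + key[3], "ERN" + key[4]
        feats[key] = between_network_mean(m, pmap, a, b)
    return {k: feats[k] for k in FEATURE_KEYS}


def extract_features_table(
    matrices: dict[str, ConnectivityMatrix], pmap: NetworkParcelMap
) -> pd.DataFrame:
    """Feature rows for a set of subjects, indexed by subject id."""
    rows = {sid: extract_features(m, pmap) for sid, m in matrices.items()}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_KEYS))
    out.index.name = "subject"
    return out


def read_matrix_directory(directory: str | Path) -> dict[str, ConnectivityMatrix]:
    """Load every ``<subject>.tsv`` matrix in a directory, keyed by subject id."""
    directory = Path(directory)
    out = {}
    for p in sorted(directory.glob("*.tsv")):
        out[p.stem] = ConnectivityMatrix.from_tsv(p)
    if not out:
        raise ConnectivityError(f"no matrix TSVs found in {directory}")
    return out
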
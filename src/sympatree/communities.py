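"""Survey ingestion, taxon pooling, and pairwise geographic/environmental
distance structures.

Survey records come from heterogeneous literature sources in which taxa not
identified to species level carry inconsistent morphotype tags ("sp.",
"sp. 1", "cf. xyz", ...).  Two pooling rules are supported:

* ``small``  — morphotypes with the same canonical tag in the same genus (or
  family) are merged across surveys;
* ``large``  — every morphotype is kept separate per survey (suffixed with
  the survey id), giving an upper bound on the taxon count.

Fully identified binomials always merge across surveys under both rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurveyRecord",
    "CommunityMatrix",
    "pool_taxa",
    "canonical_morphotype",
    "haversine_km",
    "geo_distance_matrix",
    "env_difference_matrix",
    "build_pair_table",
    "to_square",
    "EARTH_RADIUS_KM",
    "SITE_COLUMNS",
    "HABITATS",
]

EARTH_RADIUS_KM = 6371.0

#: site-metadata table columns: decimal degrees, deg C, mm, habitat code
SITE_COLUMNS = ["community", "latitude", "longitude", "mat", "map", "habitat"]
HABITATS = ("SSF", "EDF", "EMF")

IDENTIFICATION_LEVELS = ("species", "genus", "family")


@dataclass(frozen=True)
class SurveyRecord:
    survey: str
    family: Optional[str]
    genus: Optional[str]
    terminal: str  # species epithet, binomial tail, or morphotype tag
    level: str = "species"
    abundance: int = 1

    def __post_init__(self):
        if self.level not in IDENTIFICATION_LEVELS:
            raise ValueError(f"unknown identification level {self.level!r}")
        if not isinstance(self.abundance, (int, np.integer)) or self.abundance < 1:
            raise ValueError("abundance must be a positive integer")


def canonical_morphotype(tag: str) -> str:
    """Map literature morphotype spellings onto a canonical key.

    "sp.", "sp", "" -> "sp"; "sp. 1", "sp1", "sp_1" -> "sp1";
    "cf. foo" -> "cf_foo".  The key distinguishes distinct tags and merges
    spelling variants of the same tag.
    """
    t = tag.strip().lower().replace(".", " ").replace("_", " ")
    t = re.sub(r"(?<=[a-z])(?=\d)", " ", t)  # "sp1" -> "sp 1"
    t = re.sub(r"\s+", " ", t).strip()
    if not t:
        return "sp"
    m = re.fullmatch(r"(sp|spp|indet|cf|aff)(?: (\S.*))?", t)
    if m:
        head, rest = m.groups()
        head = "sp" if head == "spp" else head
        if rest is None:
            return head
        if rest.isdigit():
            return f"{head}{int(rest)}"
        return f"{head}_{rest.replace(' ', '_')}"
    if t.isdigit():
        return f"sp{int(t)}"
    return t.replace(" ", "_")


def _taxon_label(rec: SurveyRecord, mode: str, index: int) -> str:
    def cap(s: str) -> str:
        s = re.sub(r"\s+", "_", s.strip())
        return s[:1].upper() + s[1:].lower() if s else s

    if rec.level == "species":
        if not rec.genus:
            raise ValueError(f"record {index}: species-level record without genus")
        epithet = re.sub(r"\s+", "_", rec.terminal.strip().lower())
        return f"{cap(rec.genus)}_{epithet}"
    if rec.level == "genus":
        if not rec.genus:
            raise ValueError(f"record {index}: genus-level record without genus")
        label = f"{cap(rec.genus)}_{canonical_morphotype(rec.terminal)}"
    else:  # family
        if not rec.family:
            raise ValueError(f"record {index}: family-level record without family")
        tag = canonical_morphotype(rec.terminal)
        if tag == "sp" or tag.startswith("sp") and tag[2:].isdigit():
            tag = "indet" + tag[2:]
        label = f"{cap(rec.family)}_{tag}"
    if mode == "large":
        label = f"{label}__{rec.survey}"
    return label


class CommunityMatrix:
    """Communities x taxa abundance matrix (non-negative integers).

    Community order is fixed by first appearance in the input records; taxon
    labels are unique.  Alpha/beta metrics downstream use presence-absence.
    """

    def __init__(self, ids: Sequence[str], taxa: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix)
        if matrix.shape != (len(ids), len(taxa)):
            raise ValueError("matrix shape disagrees with ids/taxa")
        if np.any(matrix < 0):
            raise ValueError("negative abundance")
        if len(set(taxa)) != len(taxa):
            raise ValueError("taxon labels not unique")
        if np.any(matrix.sum(axis=1) == 0):
            empty = [ids[i] for i in np.flatnonzero(matrix.sum(axis=1) == 0)]
            raise ValueError(f"empty communities: {empty}")
        self.ids = list(ids)
        self.taxa = list(taxa)
        self.matrix = matrix.astype(int)
        self._row = {c: i for i, c in enumerate(self.ids)}

    @property
    def n_communities(self) -> int:
        return len(self.ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def taxa_of(self, community: str) -> list[str]:
        row = self.matrix[self._row[community]]
        return [self.taxa[j] for j in np.flatnonzero(row > 0)]

    def presence(self) -> np.ndarray:
        return self.matrix > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.taxa)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CommunityMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())


def pool_taxa(records: Sequence[SurveyRecord], mode: str = "small") -> CommunityMatrix:
    """Build the community matrix under the small/large pooling rule."""
    if mode not in ("small", "large"):
        raise ValueError(f"mode must be 'small' or 'large', got {mode!r}")
    if not records:
        raise ValueError("no survey records")
    counts: dict[tuple[str, str], int] = {}
    ids: list[str] = []
    taxa: list[str] = []
    seen_ids: set[str] = set()
    seen_taxa: set[str] = set()
    for i, rec in enumerate(records):
        label = _taxon_label(rec, mode, i)
        if rec.survey not in seen_ids:
            seen_ids.add(rec.survey)
            ids.append(rec.survey)
        if label not in seen_taxa:
            seen_taxa.add(label)
            taxa.append(label)
        counts[(rec.survey, label)] = counts.get((rec.survey, label), 0) + rec.abundance
    matrix = np.zeros((len(ids), len(taxa)), dtype=int)
    rowi = {c: i for i, c in enumerate(ids)}
    colj = {t: j for j, t in enumerate(taxa)}
    for (survey, label), ab in counts.items():
        matrix[rowi[survey], colj[label]] = ab
    return CommunityMatrix(ids, taxa, matrix)


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371.0 km); vectorized."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def _check_sites(sites: pd.DataFrame, cols: Iterable[str]) -> None:
    for col in cols:
        if col not in sites.columns:
            raise ValueError(f"sites table lacks column {col!r}")
        bad = sites.loc[sites[col].isna(), "community"]
        if len(bad):
            raise ValueError(f"missing {col} for community {bad.iloc[0]!r}")


def _pair_index(ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    n = len(ids)
    return np.triu_indices(n, k=1)


def geo_distance_matrix(sites: pd.DataFrame) -> pd.DataFrame:
    """Long-format table of great-circle km distances for all community pairs."""
    _check_sites(sites, ["community", "latitude", "longitude"])
    lat = sites["latitude"].to_numpy(float)
    lon = sites["longitude"].to_numpy(float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    ii, jj = _pair_index(sites["community"])
    km = haversine_km(lat[ii], lon[ii], lat[jj], lon[jj])
    ids = sites["community"].to_numpy()
    return pd.DataFrame({"comm_a": ids[ii], "comm_b": ids[jj], "km": km})


def env_difference_matrix(sites: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Absolute pairwise differences of MAT (deg C) or MAP (mm)."""
    var = variable.lower()
    if var not in ("mat", "map"):
        raise ValueError("variable must be 'MAT' or 'MAP'")
    _check_sites(sites, ["community", var])
    x = sites[var].to_numpy(float)
    ii, jj = _pair_index(sites["community"])
    ids = sites["community"].to_numpy()
    return pd.DataFrame(
        {"comm_a": ids[ii], "comm_b": ids[jj], f"d{var}": np.abs(x[ii] - x[jj])}
    )


def build_pair_table(sites: pd.DataFrame) -> pd.DataFrame:
    """km distance plus |dMAT| and |dMAP| for every unordered community pair."""
    out = geo_distance_matrix(sites)
    for var in ("mat", "map"):
        out[f"d{var}"] = env_difference_matrix(sites, var)[f"d{var}"]
    return out


def to_square(pairs: pd.DataFrame, column: str,
              ids: Optional[Sequence[str]] = None) -> tuple[np.ndarray, list[str]]:
    """Reshape a long pair table column into a symmetric zero-diagonal matrix."""
    if ids is None:
        ids = list(pd.unique(pd.concat([pairs["comm_a"], pairs["comm_b"]])))
    pos = {c: i for i, c in enumerate(ids)}
    n = len(ids)
    M = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    for a, b, v in zip(pairs["comm_a"], pairs["comm_b"], pairs[column]):
        i, j = pos[a], pos[b]
        M[i, j] = M[j, i] = v
        seen[i, j] = seen[j, i] = True
    np.fill_diagonal(seen, True)
    if not seen.all():
        raise ValueError(f"pair table incomplete for column {column!r}")
    return M, list(ids)
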
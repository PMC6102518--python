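"""File formats: Newick trees, Phylocom-style ages and sample files, and the
CSV conventions used by the survey-record and site tables.

Record CSV header: ``survey,family,genus,terminal,level,abundance``
(``level`` in {species, genus, family}).  Sites CSV header:
``community,latitude,longitude,mat,map,habitat`` (decimal degrees, deg C,
mm).  Sample files are the 3-column tab-separated Phylocom convention:
``plot<TAB>abundance<TAB>taxon``.
"""

from __future__ import annotations

import pandas as pd

from .communities import CommunityMatrix, SITE_COLUMNS, SurveyRecord
from .trees import Tree, parse_newick, write_newick

__all__ = [
    "read_newick_file",
    "write_newick_file",
    "read_records_csv",
    "read_sites_csv",
    "write_sites_csv",
    "read_sample_file",
    "write_sample_file",
]


def read_newick_file(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


def read_records_csv(path) -> list[SurveyRecord]:
    frame = pd.read_csv(path, dtype=str)
    required = {"survey", "family", "genus", "terminal", "level", "abundance"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"records CSV lacks columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            SurveyRecord(
                survey=row.survey,
                family=row.family if pd.notna(row.family) else None,
                genus=row.genus if pd.notna(row.genus) else None,
                terminal=row.terminal,
                level=row.level,
                abundance=int(row.abundance),
            )
        )
    return records


def read_sites_csv(path) -> pd.DataFrame:
    sites = pd.read_csv(path)
    missing = set(SITE_COLUMNS[:3]) - set(sites.columns)
    if missing:
        raise ValueError(f"sites CSV lacks columns: {sorted(missing)}")
    return sites


def write_sites_csv(sites: pd.DataFrame, path) -> None:
    cols = [c for c in SITE_COLUMNS if c in sites.columns]
    sites[cols].to_csv(path, index=False)


def read_sample_file(path) -> CommunityMatrix:
    """Phylocom 3-column sample file -> community matrix (order of appearance)."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["plot", "abundance", "taxon"], dtype=str)
    frame["abundance"] = frame["abundance"].astype(int)
    wide = (
        frame.pivot_table(index="plot", columns="taxon", values="abundance",
                          aggfunc="sum", fill_value=0, sort=False)
    )
    return CommunityMatrix(list(wide.index), list(wide.columns), wide.to_numpy())


def write_sample_file(matrix: CommunityMatrix, path) -> None:
    with open(path, "w") as fh:
        for i, comm in enumerate(matrix.ids):
            row = matrix.matrix[i]
            for j, ab in enumerate(row):
                if ab > 0:
                    fh.write(f"{comm}\t{int(ab)}\t{matrix.taxa[j]}\n")
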
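"""Tabular and gene-set file formats.

Peak tables, expression matrices, edge lists and association tables are
plain CSV/TSV; gene sets use the tab-separated GMT convention
(name, description, members...).  Volumes go through :mod:`braintx.volume`.
"""

from __future__ import annotations

import pandas as pd

from .meta import Peak, StudyRecord

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "read_gmt",
    "write_gmt",
    "read_edges",
    "write_edges",
]

PEAK_COLUMNS = ["study_id", "n_patients", "n_controls", "x", "y", "z", "t", "measure"]


def write_peak_table(studies: list[StudyRecord], path) -> None:
    rows = []
    for s in studies:
        if not s.peaks:
            rows.append({"study_id": s.study_id, "n_patients": s.n_patients,
                         "n_controls": s.n_controls, "x": float("nan"),
                         "y": float("nan"), "z": float("nan"),
                         "t": float("nan"), "measure": s.measure})
        for pk in s.peaks:
            rows.append({"study_id": s.study_id, "n_patients": s.n_patients,
                         "n_controls": s.n_controls, "x": pk.x, "y": pk.y,
                         "z": pk.z, "t": pk.t_value, "measure": s.measure})
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, index=False)


def read_peak_table(path) -> list[StudyRecord]:
    df = pd.read_csv(path)
    missing = set(PEAK_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path!r} lacks columns {sorted(missing)}")
    studies = []
    for sid, grp in df.groupby("study_id", sort=False):
        first = grp.iloc[0]
        peaks = [
            Peak(float(r.x), float(r.y), float(r.z), float(r.t))
            for r in grp.itertuples()
            if pd.notna(r.t)
        ]
        studies.append(
            StudyRecord(study_id=str(sid), n_patients=int(first.n_patients),
                        n_controls=int(first.n_controls), peaks=peaks,
                        measure=str(first.get("measure", "")))
        )
    return studies


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets


def write_edges(edges: pd.DataFrame, path) -> None:
    edges[["gene_a", "gene_b", "score"]].to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_a", "gene_b", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"edge list {path!r} lacks columns {sorted(missing)}")
    return df
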
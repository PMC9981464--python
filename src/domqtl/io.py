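"""Readers and writers for the package's on-disk formats.

Genotype probabilities live in an HDF5 container with one named 3-D array
per chromosome plus marker and individual index tables::

    /individuals                 (n,) strings
    /chromosomes                 ordered chromosome names
    /chr<NAME>/probs             (n, 8, m) float64
    /chr<NAME>/markers           (m,) strings
    /chr<NAME>/pos_mbp           (m,) float64

A plain-text fallback writes one CSV per chromosome with flattened
founder columns (``<marker>__<founderletter>``) and a marker position
table, producing bit-identical probabilities on read. Trait and covariate
matrices are TSV with a header row, individuals as rows and ``NA`` as the
missing token. Peaks, thresholds and allele effects round-trip through
TSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ._constants import FOUNDER_LETTERS, NA_TOKEN, N_FOUNDERS
from .errors import DataError
from .scan import AlleleEffects, Peak, PermThresholds
from .simulate import GenoProbs

__all__ = [
    "write_probs", "read_probs", "write_probs_csv", "read_probs_csv",
    "write_traits", "read_traits", "write_peaks", "read_peaks",
    "write_thresholds", "read_thresholds", "write_effects", "read_effects",
    "write_json", "read_json",
]


# ---------------------------------------------------------------------------
# genotype probabilities


def write_probs(probs: GenoProbs, path) -> None:
    probs.validate()
    with h5py.File(path, "w") as f:
        # track_times=False keeps the container byte-stable across reruns
        f.create_dataset("individuals", data=np.array(probs.individuals, dtype="S"), track_times=False)
        f.create_dataset("chromosomes", data=np.array(probs.chromosomes, dtype="S"), track_times=False)
        for chrom in probs.chromosomes:
            g = f.create_group(f"chr{chrom}")
            g.create_dataset("probs", data=probs.arrays[chrom], track_times=False)
            g.create_dataset("markers", data=probs.markers[chrom]["marker"].to_numpy(dtype="S"),
                             track_times=False)
            g.create_dataset("pos_mbp", data=probs.markers[chrom]["pos_mbp"].to_numpy(dtype=float),
                             track_times=False)


def read_probs(path) -> GenoProbs:
    try:
        with h5py.File(path, "r") as f:
            individuals = [s.decode() for s in f["individuals"][()]]
            chroms = [s.decode() for s in f["chromosomes"][()]]
            arrays, markers = {}, {}
            for chrom in chroms:
                key = f"chr{chrom}"
                if key not in f:
                    raise DataError(f"probability container missing group for chromosome {chrom!r}")
                g = f[key]
                arr = g["probs"][()]
                names = [s.decode() for s in g["markers"][()]]
                pos = g["pos_mbp"][()]
                if arr.ndim != 3 or arr.shape[0] != len(individuals) or arr.shape[1] != N_FOUNDERS:
                    raise DataError(
                        f"chromosome {chrom!r}: probs shape {arr.shape} does not match "
                        f"{len(individuals)} individuals x 8 founders"
                    )
                if arr.shape[2] != len(names) or len(names) != len(pos):
                    raise DataError(f"chromosome {chrom!r}: marker index misaligned")
                arrays[chrom] = arr
                markers[chrom] = pd.DataFrame({"marker": names, "pos_mbp": pos})
    except (OSError, KeyError) as e:
        raise DataError(f"cannot read probability container {path}: {e}") from e
    probs = GenoProbs(individuals=individuals, arrays=arrays, markers=markers)
    probs.validate(atol=1e-6)
    return probs


def write_probs_csv(probs: GenoProbs, out_dir) -> None:
    """CSV fallback: per-chromosome flattened founder columns + marker table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.Series(probs.chromosomes, name="chrom").to_csv(out / "chromosomes.csv", index=False)
    for chrom in probs.chromosomes:
        arr = probs.arrays[chrom]
        names = probs.markers[chrom]["marker"]
        cols = [f"{m}__{f}" for m in names for f in FOUNDER_LETTERS]
        flat = arr.transpose(0, 2, 1).reshape(arr.shape[0], -1)  # marker-major
        df = pd.DataFrame(flat, index=probs.individuals, columns=cols)
        df.index.name = "id"
        df.to_csv(out / f"probs_chr{chrom}.csv", float_format="%.17g")
        probs.markers[chrom].to_csv(out / f"markers_chr{chrom}.csv", index=False)


def read_probs_csv(in_dir) -> GenoProbs:
    src = Path(in_dir)
    chrom_file = src / "chromosomes.csv"
    if not chrom_file.exists():
        raise DataError(f"no chromosomes.csv in {src}")
    chroms = pd.read_csv(chrom_file)["chrom"].astype(str).tolist()
    individuals: list[str] | None = None
    arrays, markers = {}, {}
    for chrom in chroms:
        df = pd.read_csv(src / f"probs_chr{chrom}.csv", index_col="id")
        mk = pd.read_csv(src / f"markers_chr{chrom}.csv")
        mk["marker"] = mk["marker"].astype(str)
        if individuals is None:
            individuals = [str(i) for i in df.index]
        elif [str(i) for i in df.index] != individuals:
            raise DataError(f"individual order differs on chromosome {chrom!r}")
        m = len(mk)
        if df.shape[1] != m * N_FOUNDERS:
            raise DataError(f"chromosome {chrom!r}: expected {m * N_FOUNDERS} columns, got {df.shape[1]}")
        arr = df.to_numpy().reshape(len(individuals), m, N_FOUNDERS).transpose(0, 2, 1)
        arrays[chrom] = arr
        markers[chrom] = mk[["marker", "pos_mbp"]]
    assert individuals is not None
    return GenoProbs(individuals=individuals, arrays=arrays, markers=markers)


# ---------------------------------------------------------------------------
# trait / covariate tables


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="id")


def read_traits(path, kind: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV trait or covariate matrix (individuals as rows).

    The first column is the individual id; empty cells and ``NA`` are
    missing. Duplicate trait names and non-numeric cells are rejected with
    the offending address.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                          keep_default_na=False, na_values=[NA_TOKEN, ""])
    except (OSError, pd.errors.ParserError) as e:
        raise DataError(f"cannot read trait table {path}: {e}") from e
    names = header[1:]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise DataError(f"duplicate trait names in {path}: {dupes}")
    out = {}
    for col in raw.columns:
        try:
            out[col] = pd.to_numeric(raw[col])
        except (ValueError, TypeError):
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise DataError(
                f"non-numeric cell in {path}: column {col!r}, row {row!r}, value {bad.iloc[0]!r}"
            ) from None
    df = pd.DataFrame(out, index=raw.index)
    df.index.name = "id"
    df.index = df.index.astype(str)
    if kind is not None:
        df.attrs["kind"] = kind
    return df


# ---------------------------------------------------------------------------
# peaks, thresholds, effects


PEAK_COLUMNS = ["trait", "chrom", "pos_mbp", "lod", "ci_lo", "ci_hi", "marker", "marker_idx"]


def write_peaks(peaks: list[Peak], path) -> None:
    pd.DataFrame([vars(p) for p in peaks], columns=PEAK_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_peaks(path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "trait": str, "marker": str})
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"peak table {path} lacks columns {missing}")
    return [Peak(**{c: row[c] for c in PEAK_COLUMNS}) for _, row in df.iterrows()]


def write_thresholds(thr: PermThresholds, path) -> None:
    write_json(
        {
            "n_perm": thr.n_perm,
            "thresholds": {str(a): t for a, t in thr.thresholds.items()},
            "max_lods": thr.max_lods.tolist(),
        },
        path,
    )


def read_thresholds(path) -> PermThresholds:
    d = read_json(path)
    return PermThresholds(
        n_perm=int(d["n_perm"]),
        thresholds={float(a): float(t) for a, t in d["thresholds"].items()},
        max_lods=np.asarray(d["max_lods"], dtype=float),
    )


def write_effects(effects: dict[str, AlleleEffects], path) -> None:
    write_json(
        {
            name: {
                "effects": e.effects.tolist(),
                "founders": list(e.founders),
                "locus": e.locus,
                "shrunk_to_null": e.shrunk_to_null,
                "lambda": e.lambda_,
                "h2": e.h2,
            }
            for name, e in effects.items()
        },
        path,
    )


def read_effects(path) -> dict[str, AlleleEffects]:
    d = read_json(path)
    return {
        name: AlleleEffects(
            effects=np.asarray(v["effects"], dtype=float),
            founders=tuple(v["founders"]),
            locus=v["locus"],
            shrunk_to_null=bool(v["shrunk_to_null"]),
            lambda_=float(v["lambda"]),
            h2=float(v["h2"]),
        )
        for name, v in d.items()
    }


def write_json(obj, path) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True)
        f.write("\n")


def read_json(path):
    with open(path) as f:
        return json.load(f)
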
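"""On-disk cohort layout and round-tripping.

A cohort directory contains one CSV amplitude matrix and one JSON metadata
record per map, a behavior CSV, a JSON manifest, and the generating config.
All formats are plain text; write→read reproduces the in-memory values
exactly (floats serialised with `repr`-level precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .maps import ConnectivityMap, TrialSet
from .synthetic import Cohort, CohortConfig
from .zebrin import ZebrinGeometry

_FLOAT_FMT = "%.17g"


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Serialise a cohort to ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    map_records = []
    for i, m in enumerate(cohort.maps):
        mid = m.metadata.get("map_id", f"map_{i:03d}")
        np.savetxt(out / f"{mid}.csv", m.amplitudes, delimiter=",", fmt=_FLOAT_FMT)
        meta = {
            "map_id": mid,
            "condition": m.metadata.get("condition", ""),
            "subject": m.metadata.get("subject", ""),
            "site_size": m.site_size,
            "column_positions": m.column_positions.tolist(),
            "geometry": m.geometry.to_dict(),
        }
        (out / f"{mid}.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        map_records.append(mid)
        if cohort.trials:
            t = cohort.trials[i]
            flat = t.evoked.reshape(t.n_trials, -1)
            nflat = t.noise.reshape(t.n_trials, -1)
            np.savetxt(out / f"{mid}.trials.csv", flat, delimiter=",", fmt=_FLOAT_FMT)
            np.savetxt(out / f"{mid}.noise.csv", nflat, delimiter=",", fmt=_FLOAT_FMT)
    pd.DataFrame(cohort.behavior).to_csv(out / "behavior.csv", index=False)
    (out / "config.json").write_text(json.dumps(cohort.config.to_dict(), indent=1, sort_keys=True))
    manifest = {
        "maps": map_records,
        "n_maps": len(cohort.maps),
        "has_trials": bool(cohort.trials),
        "labels": cohort.labels,
        "group_codes": cohort.group_codes.tolist(),
        "features": cohort.features.tolist(),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def read_cohort(in_dir: str | Path) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    config = CohortConfig.from_dict(json.loads((src / "config.json").read_text()))
    maps, trials = [], []
    for mid in manifest["maps"]:
        amp = np.loadtxt(src / f"{mid}.csv", delimiter=",", ndmin=2)
        meta = json.loads((src / f"{mid}.json").read_text())
        maps.append(
            ConnectivityMap(
                amplitudes=amp,
                site_size=int(meta["site_size"]),
                column_positions=np.array(meta["column_positions"]),
                geometry=ZebrinGeometry.from_dict(meta["geometry"]),
                metadata={
                    "condition": meta["condition"],
                    "subject": meta["subject"],
                    "map_id": meta["map_id"],
                },
            )
        )
        if manifest["has_trials"]:
            shape = (-1,) + amp.shape
            evoked = np.loadtxt(src / f"{mid}.trials.csv", delimiter=",", ndmin=2).reshape(shape)
            noise = np.loadtxt(src / f"{mid}.noise.csv", delimiter=",", ndmin=2).reshape(shape)
            trials.append(TrialSet(evoked=evoked, noise=noise))
    behavior_df = pd.read_csv(src / "behavior.csv")
    return Cohort(
        maps=maps,
        trials=trials,
        labels=list(manifest["labels"]),
        behavior=behavior_df.to_dict("records"),
        features=np.array(manifest["features"]),
        group_codes=np.array(manifest["group_codes"]),
        config=config,
    )


def write_feature_table(path: str | Path, map_ids, labels, scheme: str, vectors) -> None:
    """One CSV row per map with scheme-tagged feature columns."""
    vectors = np.asarray(vectors, dtype=float)
    cols = [f"{scheme}_{i}" for i in range(vectors.shape[1])]
    df = pd.DataFrame(vectors, columns=cols)
    df.insert(0, "map_id", list(map_ids))
    df.insert(1, "condition", list(labels))
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path):
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns if c not in ("map_id", "condition")]
    return df["map_id"].tolist(), df["condition"].tolist(), df[value_cols].to_numpy()
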
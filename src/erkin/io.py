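"""CSV/JSON readers and writers for the pipeline's artifacts.

Formats:

* time courses — long CSV with columns ``replicate,time,species,value``
  (species in {S0, S1, S2}; the measured channels physically correspond to
  S0+C1, S1+C2 and S2, with the complex contributions negligible at the
  experimental enzyme level);
* trajectories — long CSV ``time,species,value``;
* parameter sets — flat JSON keyed by symbol names;
* posterior clouds — CSV ``kappa1,kappa2,pi,sigma`` plus a JSON sidecar
  with variant, seed and diagnostics;
* barcodes — CSV ``dim,birth,death`` with the literal ``inf`` for essential
  classes;
* labelled matrices — CSV with labels as header and index.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .identifiability import TimeCourseData
from .inference import PosteriorCloud
from .models import ExperimentDesign
from .tda import Barcode

SPECIES = ("S0", "S1", "S2")


def timecourse_to_csv(z: TimeCourseData, path: str | Path) -> None:
    rows = []
    for rep in range(z.design.replicates):
        for ti, t in enumerate(z.design.times):
            for si, sp in enumerate(SPECIES):
                rows.append((rep + 1, t, sp, z.values[si, ti, rep]))
    pd.DataFrame(rows, columns=["replicate", "time", "species", "value"]).to_csv(
        path, index=False
    )


def timecourse_from_csv(
    path: str | Path,
    S_tot: float = 5.0,
    E_tot: float = 0.65,
    label: str = "",
) -> TimeCourseData:
    df = pd.read_csv(path)
    required = {"replicate", "time", "species", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"time-course CSV needs columns {sorted(required)}")
    times = tuple(sorted(df["time"].unique()))
    reps = sorted(df["replicate"].unique())
    design = ExperimentDesign(times, len(reps), S_tot=S_tot, E_tot=E_tot, label=label)
    values = np.full((3, len(times), len(reps)), np.nan)
    t_idx = {t: i for i, t in enumerate(times)}
    r_idx = {r: i for i, r in enumerate(reps)}
    s_idx = {s: i for i, s in enumerate(SPECIES)}
    for _, row in df.iterrows():
        values[s_idx[row["species"]], t_idx[row["time"]], r_idx[row["replicate"]]] = row[
            "value"
        ]
    if np.any(np.isnan(values)):
        raise ValueError("time-course CSV is not a complete 3 x l x r grid")
    return TimeCourseData(values, design)


def trajectory_to_csv(
    times: Sequence[float], traj: np.ndarray, path: str | Path,
    species: Sequence[str] = SPECIES,
) -> None:
    """Write a (len(times), n_species) trajectory as long CSV."""
    traj = np.asarray(traj)
    rows = [
        (t, sp, traj[ti, si])
        for ti, t in enumerate(times)
        for si, sp in enumerate(species)
    ]
    pd.DataFrame(rows, columns=["time", "species", "value"]).to_csv(path, index=False)


def params_to_json(params, path: str | Path) -> None:
    data = dataclasses.asdict(params)
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def cloud_to_csv(cloud: PosteriorCloud, path: str | Path) -> None:
    base = Path(path)
    pd.DataFrame(cloud.samples, columns=list(cloud.param_names)).to_csv(
        base, index=False
    )
    sidecar = {
        "variant": cloud.variant,
        "seed": cloud.seed,
        "n_chains": cloud.n_chains,
        "diagnostics": cloud.diagnostics,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def barcodes_to_csv(barcodes: Sequence[Barcode], path: str | Path) -> None:
    rows = []
    for bc in barcodes:
        for birth, death in bc.bars:
            rows.append((bc.k, birth, "inf" if death == float("inf") else death))
    pd.DataFrame(rows, columns=["dim", "birth", "death"]).to_csv(path, index=False)


def matrix_to_csv(
    labels: Sequence[str], matrix: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels)).to_csv(
        path
    )


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_coerce) + "\n")


def _coerce(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
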
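"""Reading and writing the on-disk layouts.

Pattern datasets travel as a tab-delimited trials x voxels matrix plus a
JSON sidecar carrying the trial labels and provenance; an optional NIfTI
path maps a 4-D volume series with a matching events table into a
:class:`PatternDataset`.  Behavioral sessions and trial designs are
tab-delimited tables with a one-line header.  Configs load from JSON or
YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import BehavioralSession, ComparisonTrial
from .cohort import CohortConfig
from .dataset import PatternDataset


def write_dataset(ds: PatternDataset, basepath: str | Path) -> None:
    """Write ``<base>.tsv`` (matrix) and ``<base>.json`` (labels sidecar)."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(base.with_suffix(".tsv"), ds.betas, delimiter="\t",
               fmt="%.17g")
    sidecar = {
        "participant_id": ds.participant_id,
        "roi_name": ds.roi_name,
        "normalized": ds.normalized,
        "labels": ds.labels.to_dict(orient="records"),
        "voxel_tstats": None if ds.voxel_tstats is None
        else ds.voxel_tstats.tolist(),
        "voxel_provenance": [list(p) for p in ds.voxel_provenance],
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar))


def read_dataset(basepath: str | Path) -> PatternDataset:
    base = Path(basepath)
    betas = np.loadtxt(base.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    try:
        sidecar = json.loads(base.with_suffix(".json").read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"malformed sidecar {base.with_suffix('.json')}: "
                         f"{err}") from err
    labels = pd.DataFrame(sidecar["labels"])
    if len(labels) != betas.shape[0]:
        raise ValueError(
            f"sidecar has {len(labels)} trial labels but the matrix has "
            f"{betas.shape[0]} rows"
        )
    tstats = sidecar.get("voxel_tstats")
    return PatternDataset(
        betas=betas,
        labels=labels,
        participant_id=sidecar["participant_id"],
        roi_name=sidecar["roi_name"],
        normalized=sidecar["normalized"],
        voxel_tstats=None if tstats is None else np.asarray(tstats),
        voxel_provenance=[tuple(p) for p in sidecar["voxel_provenance"]],
    )


def read_nifti_dataset(
    nifti_path: str | Path,
    events_path: str | Path,
    participant_id: str = "sub-00",
    roi_name: str = "roi",
) -> PatternDataset:
    """Load one NIfTI volume per trial (4-D series) plus an events table.

    The events table (TSV) must have one row per volume with at least
    ``numerosity``, ``format`` and ``task`` columns.  All voxels of each
    volume are flattened into one pattern row.
    """
    import nibabel as nib  # optional dependency

    img = nib.load(str(nifti_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI series (one volume per trial)")
    n_trials = data.shape[3]
    betas = data.reshape(-1, n_trials).T.astype(float)
    events = pd.read_csv(events_path, sep="\t")
    if len(events) != n_trials:
        raise ValueError(
            f"events table has {len(events)} rows but the series has "
            f"{n_trials} volumes"
        )
    return PatternDataset(betas=betas, labels=events,
                          participant_id=participant_id, roi_name=roi_name)


def write_behavior(session: BehavioralSession, path: str | Path) -> None:
    rows = [dict(n1=t.n1, n2=t.n2, correct=int(t.correct), rt_ms=t.rt_ms)
            for t in session.trials]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_behavior(path: str | Path,
                  participant_id: str = "sub-00") -> BehavioralSession:
    df = pd.read_csv(path, sep="\t")
    trials = [ComparisonTrial(n1=int(r.n1), n2=int(r.n2),
                              correct=bool(r.correct), rt_ms=float(r.rt_ms))
              for r in df.itertuples()]
    return BehavioralSession(trials=trials, participant_id=participant_id)


def load_config(path: str | Path) -> CohortConfig:
    """Read a cohort config from JSON or YAML (keyed by field name)."""
    text = Path(path).read_text()
    blob = json.loads(text) if str(path).endswith(".json") \
        else yaml.safe_load(text)
    return CohortConfig(**blob)
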
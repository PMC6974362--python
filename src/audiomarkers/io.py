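"""Runtime serialization of epochs, recordings, and pupil sessions.

Epoch matrices and continuous recordings go to .npz array containers with the
stimulus parameters stored as scalar entries; pupil sessions and cohort tables
are delimited text (CSV).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fmfr import EpochedResponse
from .ipdfr import ContinuousRecording
from .pupil import PupilSession, PupilTrace
from .stimuli import FMStimulusSpec, IPDStimulusSpec


def save_epochs(path, resp: EpochedResponse):
    meta = {}
    if isinstance(resp.stimulus_spec, FMStimulusSpec):
        meta = {f"stim_{k}": v for k, v in resp.stimulus_spec.__dict__.items()}
    np.savez(path, epochs_pos=resp.epochs_pos, epochs_neg=resp.epochs_neg,
             sample_rate_hz=resp.sample_rate_hz, **meta)


def load_epochs(path) -> EpochedResponse:
    with np.load(path) as z:
        stim = None
        if "stim_carrier_hz" in z:
            kwargs = {k[5:]: z[k].item() for k in z.files if k.startswith("stim_")}
            kwargs["polarity"] = int(kwargs.get("polarity", 1))
            stim = FMStimulusSpec(**kwargs)
        return EpochedResponse(z["epochs_pos"], z["epochs_neg"],
                               float(z["sample_rate_hz"]), stimulus_spec=stim)


def save_recording(path, rec: ContinuousRecording):
    meta = {}
    if isinstance(rec.stimulus_spec, IPDStimulusSpec):
        meta = {f"stim_{k}": v for k, v in rec.stimulus_spec.__dict__.items()}
    np.savez(path, samples=rec.samples, sample_rate_hz=rec.sample_rate_hz,
             **meta)


def load_recording(path) -> ContinuousRecording:
    with np.load(path) as z:
        stim = None
        if "stim_carrier_hz" in z:
            kwargs = {k[5:]: z[k].item() for k in z.files if k.startswith("stim_")}
            kwargs["control_mode"] = str(kwargs.get("control_mode", "opposing"))
            stim = IPDStimulusSpec(**kwargs)
        return ContinuousRecording(z["samples"], float(z["sample_rate_hz"]),
                                   stimulus_spec=stim)


def save_pupil_session(path, session: PupilSession):
    rows = []
    for i, tr in enumerate(session.trials):
        for j in range(len(tr.diameter)):
            rows.append((i, tr.block, tr.snr_db, j, tr.diameter[j],
                         int(tr.missing[j])))
    df = pd.DataFrame(rows, columns=["trial", "block", "snr_db", "sample",
                                     "diameter", "missing"])
    df.attrs["light_range"] = session.light_range
    df.insert(0, "light_range", session.light_range)
    df.to_csv(path, index=False)


def load_pupil_session(path) -> PupilSession:
    df = pd.read_csv(path)
    trials = []
    for _, g in df.groupby("trial", sort=True):
        g = g.sort_values("sample")
        trials.append(PupilTrace(g["diameter"].to_numpy(),
                                 g["missing"].to_numpy(dtype=bool),
                                 float(g["snr_db"].iloc[0]),
                                 int(g["block"].iloc[0])))
    return PupilSession(trials, float(df["light_range"].iloc[0]))
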
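import numpy as np
import pandas as pd
import pytest

from pkgfluct import DoseEvent, SubjectRecording


def build_recording(
    bks,
    dks=None,
    start="2024-03-04 00:00",
    worn=None,
    tremor=None,
    walking=None,
    dose_clocks=(),
    subject_id="T1",
):
    """Small recording on a contiguous 2-min grid with optional dose
    reminders at the given clock times on every covered date."""
    bks = np.asarray(bks, dtype=float)
    n = len(bks)
    ts = pd.date_range(start, periods=n, freq="2min")

    def as_array(value, default):
        if value is None:
            return np.full(n, default)
        if np.isscalar(value):
            return np.full(n, value)
        return np.asarray(value)

    epochs = pd.DataFrame(
        {
            "timestamp": ts,
            "bks": bks,
            "dks": as_array(dks, 0.0).astype(float),
            "worn": as_array(worn, True).astype(bool),
            "tremor": as_array(tremor, False).astype(bool),
            "walking": as_array(walking, False).astype(bool),
        }
    )
    doses = []
    for date in ts.normalize().unique():
        for clock in dose_clocks:
            hh, mm = clock.split(":")
            doses.append(
                DoseEvent(reminder_time=(date + pd.Timedelta(hours=int(hh), minutes=int(mm))).to_pydatetime())
            )
    return SubjectRecording(subject_id=subject_id, epochs=epochs, doses=doses)


@pytest.fixture
def recording_factory():
    return build_recording
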
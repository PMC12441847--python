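import numpy as np
import pytest

from nanodst.quantile_spectra import QuantileSpectrogram, WelchParams
from nanodst.signals import (
    DeflectionRecording,
    Label,
    Phase,
    PhaseSpan,
    RecordingMeta,
)

LEVELS = np.round(np.arange(0.1, 0.95, 0.1), 10)


@pytest.fixture
def small_recording():
    """A 3-phase recording: 30 s blank, 120 s medium, 120 s drug at 200 Hz."""
    rng = np.random.default_rng(42)
    fs = 200.0
    n = int(270 * fs)
    return DeflectionRecording(
        samples=rng.standard_normal(n),
        sampling_rate=fs,
        phases=[
            PhaseSpan(Phase.BLANK, 0.0, 30.0),
            PhaseSpan(Phase.MEDIUM, 30.0, 150.0),
            PhaseSpan(Phase.DRUG, 150.0, 270.0),
        ],
        meta=RecordingMeta(
            experiment_id="fixture-1",
            cell_line="SW480",
            drug="doxorubicin",
            concentration_uM=10.0,
            label=Label.POSITIVE,
        ),
    )


def make_spectrogram(
    window_values: np.ndarray,
    freqs_hz: np.ndarray | None = None,
    window_starts_min: np.ndarray | None = None,
    levels: np.ndarray = LEVELS,
) -> QuantileSpectrogram:
    """Fabricate a spectrogram from per-(freq, window) base values.

    Level l gets base * (0.5 + l) so values are strictly increasing in level
    while keeping the fabricated structure in every level slice.
    """
    base = np.asarray(window_values, dtype=float)  # [n_freq, n_windows]
    if freqs_hz is None:
        freqs_hz = np.arange(1.0, base.shape[0] + 1.0)
    if window_starts_min is None:
        window_starts_min = 5.0 * np.arange(base.shape[1])
    values = np.stack([base * (0.5 + l) for l in levels], axis=0)
    return QuantileSpectrogram(
        values=values,
        levels=np.asarray(levels, dtype=float),
        freqs_hz=np.asarray(freqs_hz, dtype=float),
        window_starts_min=np.asarray(window_starts_min, dtype=float),
        window_min=5.0,
        welch=WelchParams(),
    )
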
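"""Optional readers for real recordings.

Only needed when loading lab data; the rest of the package never imports
this module's optional dependencies.
"""

from __future__ import annotations

import numpy as np

from .simulate import RawRecording

__all__ = ["read_brainvision"]


def read_brainvision(
    vhdr_path,
    eeg_channel: str,
    audio_channel: str,
    polarity_schedule=None,
    eeg_scale: float = 1e6,
    audio_scale: float = 1e3,
) -> RawRecording:
    """Load a BrainVision (.vhdr/.vmrk/.eeg) triad into a :class:`RawRecording`.

    Requires :mod:`mne` (not a package dependency). Channels are converted
    from MNE's volts to the package's working units (uV for EEG, mV for the
    audio monitor). ``polarity_schedule`` must be supplied by the caller
    (e.g. from the presentation log): the file itself does not record it.
    ``true_onsets`` is left empty — onsets come from
    :func:`ffrpitch.preprocessing.detect_onsets`.
    """
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("reading BrainVision files requires the 'mne' package") from e

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    eeg = raw.get_data(picks=[eeg_channel])[0] * eeg_scale
    audio = raw.get_data(picks=[audio_channel])[0] * audio_scale
    if polarity_schedule is None:
        polarity_schedule = np.array([], dtype=int)
    return RawRecording(
        eeg=eeg,
        audio=audio,
        sample_rate=float(raw.info["sfreq"]),
        polarity_schedule=np.asarray(polarity_schedule, int),
        true_onsets=np.array([], dtype=int),
        stimulus_name="",
    )
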
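"""Reading continuous recordings from delimited text or EDF files."""

from __future__ import annotations

from pathlib import Path

from .synth_eog import ContinuousRecording


def read_recording(path, fs: float = 500.0,
                   channel_map: dict[str, str] | None = None
                   ) -> ContinuousRecording:
    """Load a recording from TSV (one column per channel) or EDF.

    ``channel_map`` renames file channels to the canonical montage names
    (upperV, lowerV, Fp1, ...). EDF reading requires mne.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # optional dependency, only for EDF input

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        fs = float(raw.info["sfreq"])
        data = {name: raw.get_data(picks=[i])[0]
                for i, name in enumerate(raw.ch_names)}
    else:
        rec = ContinuousRecording.from_tsv(path, fs=fs)
        data = rec.channels
    if channel_map:
        data = {channel_map.get(k, k): v for k, v in data.items()}
    return ContinuousRecording(data, fs=fs)
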
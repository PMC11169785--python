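"""Read-only adapter for NWB files in the AJILE12 style (DANDI 000055).

Requires the optional ``pynwb`` dependency (``pip install
ecogdecode[nwb]``).  The adapter extracts the raw acquisition series,
electrode coordinates, and per-block coarse behavioral labels into the
package's :class:`~ecogdecode.containers.RawRecording`, after which
every downstream stage is identical to the synthetic path.
"""

from __future__ import annotations

import numpy as np

from .containers import RawRecording

__all__ = ["load_nwb_recording"]

try:  # pragma: no cover - optional dependency
    import pynwb  # noqa: F401
    _HAVE_PYNWB = True
except ImportError:
    _HAVE_PYNWB = False


def load_nwb_recording(path, acquisition_name: str | None = None,
                       block_duration_s: float = 120.0) -> RawRecording:
    """Load an NWB electrophysiology file as a RawRecording.

    Coarse behavior labels are read from the ``epochs`` table when
    present (one label per ``block_duration_s`` block).
    """
    if not _HAVE_PYNWB:
        raise ImportError(
            "reading NWB files requires the optional 'pynwb' dependency; "
            "install with: pip install ecogdecode[nwb]")
    from pynwb import NWBHDF5IO  # pragma: no cover

    with NWBHDF5IO(str(path), mode="r", load_namespaces=True) as io:  # pragma: no cover
        nwbfile = io.read()
        if acquisition_name is None:
            acquisition_name = next(iter(nwbfile.acquisition))
        series = nwbfile.acquisition[acquisition_name]
        data = np.asarray(series.data[:]).T  # NWB stores time x channels
        fs = float(series.rate)
        elecs = nwbfile.electrodes.to_dataframe()
        positions = elecs[["x", "y", "z"]].to_numpy(dtype=float)
        good = (elecs["good"].to_numpy(dtype=bool)
                if "good" in elecs.columns
                else np.ones(data.shape[0], dtype=bool))
        labels = None
        if nwbfile.epochs is not None:
            ep = nwbfile.epochs.to_dataframe()
            if "labels" in ep.columns:
                labels = [str(x) for x in ep["labels"]]
        return RawRecording(data=data, fs=fs, positions=positions,
                            good_mask=good, block_duration_s=block_duration_s,
                            labels=labels)
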
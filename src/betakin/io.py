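"""File formats: HDF5 signal bundles, TSV tables, optional Merlin export.

Stage outputs are deliberately plain (HDF5 + TSV) so that any stage can be
swapped for an external tool when cross-validating.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "write_signals_h5", "read_signals_h5",
    "write_table", "read_table",
    "read_fif_pair",
    "write_merlin",
]


def write_signals_h5(path, signals: dict[tuple[str, str], np.ndarray],
                     sampling_rate: float,
                     attrs: dict[tuple[str, str], dict] | None = None) -> None:
    """Write channel-pair signals keyed by (subject, hemisphere).

    Layout: ``/<subject>/<hemisphere>`` datasets of shape (2, n); ground
    truth (when known) rides along as dataset attributes.
    """
    attrs = attrs or {}
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = sampling_rate
        for (sid, hemi), data in signals.items():
            ds = f.require_group(sid).create_dataset(hemi, data=data)
            for key, val in attrs.get((sid, hemi), {}).items():
                if val is not None and not (isinstance(val, float) and np.isnan(val)):
                    ds.attrs[key] = val


def read_signals_h5(path):
    """Inverse of :func:`write_signals_h5`.

    Returns ``(signals, sampling_rate, attrs)``.
    """
    signals: dict[tuple[str, str], np.ndarray] = {}
    attrs: dict[tuple[str, str], dict] = {}
    with h5py.File(path, "r") as f:
        rate = float(f.attrs["sampling_rate"])
        for sid in f:
            for hemi in f[sid]:
                ds = f[sid][hemi]
                signals[(sid, hemi)] = ds[()]
                attrs[(sid, hemi)] = dict(ds.attrs)
    return signals, rate, attrs


def read_fif_pair(path, channels: tuple[str, str]) -> tuple[np.ndarray, float]:
    """Adapter for real recordings: one gradiometer channel pair from a FIF
    file.

    Returns ``((2, n) data, sampling_rate)`` for the two named channels,
    ready for the spectral and event stages.
    """
    import mne

    raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    raw.pick(list(channels))
    data = raw.get_data()
    if data.shape[0] != 2:
        raise ValueError(f"expected 2 channels, found {data.shape[0]}")
    return data, float(raw.info["sfreq"])


def write_table(df: pd.DataFrame, path, index_label: str = "subject") -> None:
    df.to_csv(path, sep="\t", index=True, index_label=index_label)


def read_table(path, index_col: str = "subject") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_merlin(ped: Pedigree, table: pd.DataFrame, prefix) -> tuple[Path, Path]:
    """Export a phenotype-only pedigree in the Merlin PED/DAT dialect.

    Siblings are written as children of a dummy founder couple per family
    so relatedness is encoded through the pedigree, with missing phenotypes
    for the founders ('x'). Useful for external cross-validation of the
    variance-component fits.
    """
    prefix = Path(prefix)
    dat_path = prefix.with_suffix(".dat")
    ped_path = prefix.with_suffix(".ped")
    phenos = list(table.columns)
    dat_path.write_text("".join(f"T {p}\n" for p in phenos))
    lines = []
    for fid, members in ped.families.items():
        father, mother = f"{fid}_F", f"{fid}_M"
        blanks = " ".join(["x"] * len(phenos))
        lines.append(f"{fid} {father} 0 0 1 {blanks}")
        lines.append(f"{fid} {mother} 0 0 2 {blanks}")
        for sid in members:
            vals = []
            for p in phenos:
                v = table.at[sid, p] if sid in table.index else np.nan
                vals.append("x" if pd.isna(v) else f"{v:.6g}")
            lines.append(f"{fid} {sid} {father} {mother} 1 {' '.join(vals)}")
    ped_path.write_text("\n".join(lines) + "\n")
    return ped_path, dat_path
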
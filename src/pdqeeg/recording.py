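"""Container for multichannel resting-state EEG.

A recording is a channels-by-samples matrix in microvolts together with a
sampling rate, channel labels, unit-sphere electrode positions and a role per
channel.  Roles partition the montage:

``active``
    scalp channel entering the global (whole-head) spectral statistics.
``occipital``
    scalp channel over occipital cortex; used for the median-frequency
    biomarker *and* included in the global statistics (occipital electrodes
    are a subset of the recording montage, not a separate system).
``reference``
    the recording reference (flat by construction); excluded everywhere.
``bad``
    channel flagged as unusable; excluded until interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ROLES = ("active", "occipital", "reference", "bad")

#: roles whose channels enter scalp-level analyses
SCALP_ROLES = ("active", "occipital")


@dataclass
class EEGRecording:
    data: np.ndarray              # (n_channels, n_samples), microvolts
    sfreq: float                  # Hz
    labels: list[str]
    positions: np.ndarray         # (n_channels, 3), unit norm
    roles: list[str]              # one of ROLES per channel
    reference_label: str = "Cz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        n_ch = self.data.shape[0]
        if not (len(self.labels) == len(self.roles) == self.positions.shape[0] == n_ch):
            raise ValueError("labels/roles/positions must match channel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.sfreq <= 60.0:
            # everything downstream analyses content up to 30 Hz
            raise ValueError("sampling rate must exceed twice the highest analysis frequency (30 Hz)")
        for r in self.roles:
            if r not in ROLES:
                raise ValueError(f"unknown channel role {r!r}")
        if self.roles.count("reference") != 1:
            raise ValueError("exactly one reference channel is required")
        if self.labels[self.roles.index("reference")] != self.reference_label:
            raise ValueError("reference_label does not match the channel flagged 'reference'")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("electrode positions must lie on the unit sphere")
        if len(set(self.labels)) != n_ch:
            raise ValueError("channel labels must be unique")

    # -- convenience -------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def indices(self, *roles: str) -> np.ndarray:
        """Channel indices whose role is one of ``roles``."""
        return np.array([i for i, r in enumerate(self.roles) if r in roles], dtype=int)

    def scalp_indices(self) -> np.ndarray:
        return self.indices(*SCALP_ROLES)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        """Copy of the recording with replaced samples (metadata shared)."""
        return replace(self, data=data, labels=list(self.labels), roles=list(self.roles))

    def with_roles(self, roles: list[str]) -> "EEGRecording":
        return replace(self, data=self.data.copy(), labels=list(self.labels), roles=list(roles))

    def frontal_labels(self, fraction: float = 0.1) -> list[str]:
        """Labels of the designated frontal channels.

        By montage convention the first ``fraction`` (default 10%) of the
        non-reference channels are frontal; blink artifacts are confined to
        and removed from these.
        """
        scalp = [l for l, r in zip(self.labels, self.roles) if r != "reference"]
        k = max(1, round(fraction * len(scalp)))
        return scalp[:k]
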
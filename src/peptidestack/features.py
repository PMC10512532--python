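"""The FeatureMatrix container shared by every encoder."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    """A samples x features numeric matrix with named columns.

    Row order always matches the order of the dataset that produced it.
    """

    values: np.ndarray
    feature_names: list[str]
    encoder_name: str
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.encoder_name}: {self.values.shape[1]} columns vs "
                f"{len(self.feature_names)} feature names"
            )
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample id count")
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.encoder_name}: non-finite feature values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="id"),
            columns=self.feature_names,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, encoder_name: str = "loaded") -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns), encoder_name,
                   [str(i) for i in df.index])
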
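"""Poincare-descended difference point clouds (SODP / TODP / FODP).

The second-order difference plot (SODP) scatters consecutive first
differences of a series against each other: points
(x_{n+1} - x_n, x_{n+2} - x_{n+1}).  The third- and fourth-order plots
(TODP, FODP) extend the window to triples and quadruples of consecutive
first differences.  The clouds summarise short-term variability patterns
for visual comparison between data sets; they are translation invariant
and scale equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["DifferenceCloud", "difference_cloud"]


@dataclass(frozen=True)
class DifferenceCloud:
    """A set of order-length tuples of consecutive first differences.

    ``points`` has shape (len(series) - order, order): order 2 gives pairs
    (dx_n, dx_{n+1}), order 3 triples, order 4 quadruples.
    """

    order: int
    points: np.ndarray

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"d{i + 1}" for i in range(self.order)]
        return pd.DataFrame(self.points, columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def difference_cloud(series, order: int = 2) -> DifferenceCloud:
    """Build the order-2/3/4 difference cloud of a numeric sequence."""
    if order not in (2, 3, 4):
        raise DomainError("order must be 2 (SODP), 3 (TODP) or 4 (FODP)")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < order + 1:
        raise DomainError(
            f"series must be 1-D with length >= {order + 1} for order {order}"
        )
    dx = np.diff(x)
    windows = np.lib.stride_tricks.sliding_window_view(dx, order)
    return DifferenceCloud(order=order, points=windows.copy())
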
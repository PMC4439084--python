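"""Reference results for the three-subset immune-cell discrimination task.

The table below is the reported leave-one-out confusion matrix for
discriminating CD4+ T lymphocytes, CD8+ T lymphocytes and CD56+ natural
killer cells by wavelength-modulated Raman spectroscopy (638 cells in all,
three donors).  Rows are actual classes, columns predicted.  It serves as a
worked reference for the summary arithmetic in :mod:`wmrs.classify` — note
the diagonal dominance and the heavy CD4/CD8 cross-talk typical of these two
closely related lineages.
"""

import numpy as np

from .classify import ConfusionMatrix

__all__ = ["THREE_SUBSET_CONFUSION"]

THREE_SUBSET_CONFUSION = ConfusionMatrix(
    class_order=("CD4+", "CD8+", "CD56+"),
    counts=np.array(
        [
            [135, 84, 12],
            [81, 149, 1],
            [24, 4, 148],
        ]
    ),
)
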
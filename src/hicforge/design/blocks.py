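"""Assembly-block decomposition of a redesigned sequence."""
from __future__ import annotations

import math
from typing import List, Tuple, Union

from .records import SequenceRecord


def split_blocks(
    seq: Union[str, SequenceRecord, int], block_size: int = 3000, overlap: int = 200
) -> List[Tuple[int, int, int]]:
    """Overlapping blocks ``(index, start, end)`` covering the sequence.

    Block *i* covers ``[i*(block_size-overlap), i*(block_size-overlap)+block_size)``
    clipped at the sequence end; consecutive blocks share exactly ``overlap``
    bp (except possibly at the last one).  ``seq`` may be a sequence, a
    record, or a bare length.
    """
    if not block_size > overlap >= 0:
        raise ValueError("need block_size > overlap >= 0")
    if isinstance(seq, int):
        L = seq
    elif isinstance(seq, SequenceRecord):
        L = len(seq)
    else:
        L = len(seq)
    if L <= overlap:
        return [(0, 0, L)]
    stride = block_size - overlap
    n = math.ceil((L - overlap) / stride)
    out = []
    for i in range(n):
        start = i * stride
        out.append((i, start, min(start + block_size, L)))
    return out
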
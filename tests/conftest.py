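"""Shared test configuration.

BLAS threading is pinned to one thread before numpy loads: parallel
reductions change floating-point accumulation order, which the nonconvex
fitting trajectories amplify, so pinning keeps every fit bit-reproducible
across machines and core counts.
"""

import os

for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS",
             "NUMEXPR_NUM_THREADS"):
    os.environ.setdefault(_var, "1")
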
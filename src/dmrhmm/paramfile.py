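"""Plain-text key=value serialization of fitted model parameters.

One file holds both per-sample beta mixtures and the learned HMM transition
parameters, so a ``fit`` run can be reused by later ``detect`` runs.
"""

from __future__ import annotations

import numpy as np

from .hmm import N_CPG, HmmParams
from .mixture import BetaMixture


def _mix_items(prefix: str, mix: BetaMixture):
    yield f"{prefix}.w_h", mix.w_h
    yield f"{prefix}.w_l", mix.w_l
    yield f"{prefix}.w_unif", mix.w_unif
    yield f"{prefix}.alpha_h", mix.alpha_h
    yield f"{prefix}.beta_l", mix.beta_l


def write_params(path, mix1: BetaMixture, mix2: BetaMixture,
                 hmm: HmmParams | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# dmrhmm fitted parameters\n")
        for prefix, mix in (("mix1", mix1), ("mix2", mix2)):
            for key, val in _mix_items(prefix, mix):
                fh.write(f"{key}={float(val)!r}\n")
        if hmm is not None:
            for s in range(N_CPG):
                fh.write(f"hmm.gap_stay.{s}={float(hmm.gap_stay[s])!r}\n")
                fh.write(f"hmm.initial.{s}={float(hmm.initial[s])!r}\n")
                for t in range(N_CPG):
                    fh.write(f"hmm.gap_to_cpg.{s}.{t}={float(hmm.gap_to_cpg[s, t])!r}\n")


def read_params(path):
    """Returns (mix1, mix2, hmm_or_None)."""
    kv: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = float(val)

    def mix(prefix):
        return BetaMixture(w_h=kv[f"{prefix}.w_h"], w_l=kv[f"{prefix}.w_l"],
                           w_unif=kv[f"{prefix}.w_unif"],
                           alpha_h=kv[f"{prefix}.alpha_h"],
                           beta_l=kv[f"{prefix}.beta_l"])

    hmm = None
    if "hmm.gap_stay.0" in kv:
        stay = np.array([kv[f"hmm.gap_stay.{s}"] for s in range(N_CPG)])
        init = np.array([kv[f"hmm.initial.{s}"] for s in range(N_CPG)])
        q = np.array([[kv[f"hmm.gap_to_cpg.{s}.{t}"] for t in range(N_CPG)]
                      for s in range(N_CPG)])
        # repr round-trips floats exactly; renormalize defensively anyway
        q = q / q.sum(axis=1, keepdims=True)
        hmm = HmmParams(gap_stay=stay, gap_to_cpg=q, initial=init / init.sum())
    return mix("mix1"), mix("mix2"), hmm
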
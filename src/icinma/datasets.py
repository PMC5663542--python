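"""Shipped evidence tables and the treatment registry for the melanoma network.

Ten treatment strategies are compared: chemotherapy (the network reference),
two anti-CTLA-4 antibodies (ipilimumab, tremelimumab), two anti-PD-1
antibodies (nivolumab, pembrolizumab) and five ipilimumab combinations.  The
gp100 vaccine alone appears only as the reference arm of one three-arm trial
and is carried as an auxiliary, non-reportable node.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .data import (
    EvidenceNetwork,
    RiskFlags,
    Treatment,
    load_risk_flags,
    load_trial_table,
    merge_dose_arms,
    resolve_auxiliary_nodes,
)

_TREATMENTS = [
    Treatment("CHE", "chemotherapy"),
    Treatment("IPI", "ipilimumab"),
    Treatment("TRE", "tremelimumab"),
    Treatment("NIV", "nivolumab"),
    Treatment("PEM", "pembrolizumab"),
    Treatment("IPI_CHE", "ipilimumab plus chemotherapy"),
    Treatment("IPI_NIV", "ipilimumab plus nivolumab"),
    Treatment("IPI_GP100", "ipilimumab plus gp100"),
    Treatment("IPI_BUD", "ipilimumab plus budesonide"),
    Treatment("IPI_SAR", "ipilimumab plus sargramostim"),
    Treatment("GP100", "gp100 peptide vaccine", reportable=False),
]

REFERENCE = "CHE"


def treatment_registry() -> dict[str, Treatment]:
    return {t.id: t for t in _TREATMENTS}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("icinma").joinpath("data").joinpath(name)))


def trial_table_path() -> Path:
    """Path of the shipped per-arm PFS evidence table (12 trials)."""
    return _data_path("melanoma_pfs.csv")


def risk_flags_path() -> Path:
    """Path of the shipped (synthetic) risk-of-bias flag table."""
    return _data_path("risk_flags_synthetic.csv")


def load_melanoma_network(
    dose_policy: str = "pool", aux_policy: str = "aux_node"
) -> EvidenceNetwork:
    """The analysis-ready melanoma PFS network.

    Default policies mirror the primary analysis: same-treatment dose arms are
    pooled by inverse variance into a single node contrast, and the gp100-alone
    arm is kept as a likelihood-only auxiliary node.
    """
    net = load_trial_table(trial_table_path(), schema="PFS")
    net = merge_dose_arms(net, policy=dose_policy)
    return resolve_auxiliary_nodes(net, policy=aux_policy)


def load_melanoma_risk_flags() -> RiskFlags:
    return load_risk_flags(risk_flags_path())
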
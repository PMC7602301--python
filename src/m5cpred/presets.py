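"""Per-species presets: optimal feature subsets, gap K defaults, dataset shapes.

These bundle the published per-species configurations: the SFS-selected
feature subset, the gap K chosen for KSNPF/KSPSDP, the window flank
(lambda = 20 throughout), and the benchmark dataset shapes used as
defaults by the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass

from .features import FeatureSpec


@dataclass(frozen=True)
class SpeciesPreset:
    name: str
    subset: tuple[str, ...]        # report-style family names, SFS order
    ksnpf_k: int
    kspsdp_k: int
    lambda_flank: int
    n_train_per_class: int
    n_test_per_class: int

    def feature_spec(self, lambda_pse: int = 2, w: float = 0.1) -> FeatureSpec:
        return FeatureSpec.parse(self.subset, lambda_pse=lambda_pse, w=w)


PRESETS: dict[str, SpeciesPreset] = {
    "h_sapiens": SpeciesPreset(
        name="h_sapiens",
        subset=("PSNP", "4NF", "5SNPF", "PseDNC"),
        ksnpf_k=5, kspsdp_k=5,
        lambda_flank=20,
        n_train_per_class=200, n_test_per_class=69,
    ),
    "m_musculus": SpeciesPreset(
        name="m_musculus",
        subset=("CPD", "4NF", "1SPSDP"),
        ksnpf_k=1, kspsdp_k=1,
        lambda_flank=20,
        n_train_per_class=4563, n_test_per_class=1000,
    ),
    "a_thaliana": SpeciesPreset(
        name="a_thaliana",
        subset=("PseDNC", "3SPSDP", "4NF", "1SNPF", "PSNP"),
        ksnpf_k=1, kspsdp_k=3,
        lambda_flank=20,
        n_train_per_class=5289, n_test_per_class=1000,
    ),
}

#: Gap grid exposed for re-selecting K per species (single-family CV sweep).
DEFAULT_K_GRID = list(range(0, 11))


def get_preset(name: str) -> SpeciesPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown species preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
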
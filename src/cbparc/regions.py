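"""Named target-region conventions shared across modules."""

from __future__ import annotations

#: The 19 cross-species homologous target regions used for connectivity
#: fingerprints (motor, somatosensory, auditory/language, memory and
#: higher-cognitive areas present in both the human and the macaque cortex).
HOMOLOG_TARGETS_19: tuple[str, ...] = (
    "9/46d",
    "44v",
    "SMA",
    "8m",
    "M1",
    "S1",
    "ParOp",
    "aIPS",
    "pIPS",
    "pIPL",
    "23ab",
    "rsplC",
    "perirhinal",
    "ventrStr",
    "hippoc",
    "35/36r",
    "9m",
    "8dL",
    "granular insula",
)


def default_target_names(n_targets: int) -> list[str]:
    """Target names for a fingerprint of length ``n_targets``.

    The canonical 19-region homolog set when ``n_targets == 19``; otherwise
    generic ``target_01..`` placeholders.
    """
    if n_targets == len(HOMOLOG_TARGETS_19):
        return list(HOMOLOG_TARGETS_19)
    return [f"target_{i + 1:02d}" for i in range(n_targets)]
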
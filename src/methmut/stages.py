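"""The fixed 13-stage ordering of the germline developmental methylomes.

Stages run from mature gametes through pre-implantation embryos to
primordial germ cells (PGC) labelled by gestational week and sex
(e.g. ``PGC11wf`` = 11-week female). Every pattern string, regression
table and report in the package uses this order.
"""

STAGES: tuple[str, ...] = (
    "sperm",
    "oocyte",
    "8cell",
    "morula",
    "ICM",
    "PGC7wm",
    "PGC10wm",
    "PGC10wf",
    "PGC11wm",
    "PGC11wf",
    "PGC13wm",
    "PGC17wf",
    "PGC19wm",
)

N_STAGES = len(STAGES)

STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


def validate_stages(stage_ids) -> None:
    """Raise ValueError unless *stage_ids* is exactly the canonical 13."""
    missing = [s for s in STAGES if s not in set(stage_ids)]
    extra = [s for s in stage_ids if s not in STAGE_INDEX]
    if missing or extra:
        raise ValueError(
            f"expected the 13 canonical stages; missing={missing}, unknown={extra}"
        )
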
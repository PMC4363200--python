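"""Run configuration.

Every numeric threshold of the method lives here, with defaults equal to
the published values of the original method where one is stated, and to
a documented package design choice otherwise (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    # --- randomness / mode -------------------------------------------------
    seed: int = 1
    stranded: bool = True
    verbosity: int = 1

    # --- stage 1 self-training restrictions --------------------------------
    min_cds_train: int = 600       # CDS training examples must be >= this many nt
    max_utr_orf: int = 300         # ORFs >= this long are excised from UTR examples
    retrain_iterations: int = 2    # fixed number of retraining passes

    # --- stage 1 model structure -------------------------------------------
    kozak_window: int = 11         # WAM window, up to and including the ATG
    kozak_order: int = 2
    cds_order: int = 5             # three-periodic coding chain
    utr_order: int = 5             # non-periodic UTR / noncoding chains
    separate_utr_tables: bool = False   # default: one shared UTR table
    min_gene_nt: int = 6           # smallest decodable CDS between ATG and stop

    # --- emission / duration numerics --------------------------------------
    pseudocount: float = 0.01
    n_floor_logprob: float = -1.3862943611198906  # log(1/4): score of N-context bases
    order_quota: int = 50          # need >= quota * 4**k events to keep order k
    duration_bandwidth: int = 0    # 0 -> auto: max(2, support_width // 50)

    # --- stage 2 intron model ----------------------------------------------
    donor_max: int = 22            # max total donor length incl. 2 exon nt
    acceptor_max: int = 22
    exon_extension: int = 2        # splice WAMs extend this far into the exon
    chi2_p: float = 0.01           # boundary-length fit significance
    min_introns_for_fit: int = 50
    default_donor_len: int = 11    # fallback total incl. exon nt (9 intronic + 2)
    default_acceptor_len: int = 11
    interior_margin: int = 22      # intron interior excludes this much at each end
    branch_width: int = 7
    branch_search_min: int = 6     # branch window ends within [min,max] nt of the AG
    branch_search_max: int = 50
    spacer_order: int = 2
    min_intron: int = 20
    intron_cap: int = 5000
    intron_factor: float = 1.1
    default_max_intron: int = 1000
    disable_intron_cap: bool = False
    relax_nt: int = 50             # boundary constraint relaxed near transcript ends
    flank_pad: int = 200           # genomic-window padding around selected loci
    retrain_cds_stage2: bool = False   # default: copy stage-1 coding tables
    min_stage2_odds: float = 0.0   # stage-2 genes must beat the intergenic
                                   # model over their span by this many nats
    min_intron_odds: float = 0.0   # each predicted intron must beat the
                                   # intergenic model over its span

    # --- post-prediction filters -------------------------------------------
    min_protein_aa: int = 30       # genes translating to fewer aa are removed
    variant_unique_aa: int = 10
    nested_outside_frac: float = 0.2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "min_cds_train", "max_utr_orf", "kozak_window", "pseudocount",
            "donor_max", "acceptor_max", "chi2_p", "min_introns_for_fit",
            "branch_width", "min_intron", "intron_cap", "intron_factor",
            "default_max_intron", "relax_nt", "flank_pad", "min_protein_aa",
            "variant_unique_aa", "nested_outside_frac",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"config value {name!r} must be positive")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0 (zero gives -inf scores)")
        if self.kozak_window < 3:
            raise ConfigError("kozak_window must cover at least the ATG codon")

    # --- serialisation ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)
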
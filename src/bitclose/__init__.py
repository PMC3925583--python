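"""bitclose: frequent closed itemsets and inclusion-maximal biclusters of
binary matrices, mined level-wise with bit-table matrix algebra."""

from .core import (
    Bicluster,
    BitcloseError,
    BitTable,
    ConfigError,
    ContractViolationError,
    IndexTable,
    InvalidInputError,
    Itemset,
    MemoryGuardError,
    MiningConfig,
    SupportMatrix,
    TransactionDB,
    column_support,
    hadamard_column,
    pairwise_supports,
)
from .miner import LevelResult, frequent_singletons, join_candidates, mine_frequent, prune
from .closed import extract_closed, itemset_to_bicluster, verify_closedness
from .binarize import ExpressionMatrix, binarize, read_expression
from .oracle import (
    enumerate_closed_bruteforce,
    enumerate_frequent_bruteforce,
    enumerate_maximal_biclusters_bruteforce,
)
from .synthio import implant_blocks, random_binary

__version__ = "0.1.0"


def mine_closed(B0: BitTable, cfg: MiningConfig) -> list[Itemset]:
    """Convenience pipeline: mine all frequent itemsets, keep the closed ones."""
    return extract_closed(mine_frequent(B0, cfg), cfg)


__all__ = [
    "__version__",
    "BitcloseError",
    "InvalidInputError",
    "ConfigError",
    "ContractViolationError",
    "MemoryGuardError",
    "TransactionDB",
    "BitTable",
    "SupportMatrix",
    "IndexTable",
    "Itemset",
    "Bicluster",
    "MiningConfig",
    "column_support",
    "pairwise_supports",
    "hadamard_column",
    "LevelResult",
    "frequent_singletons",
    "join_candidates",
    "prune",
    "mine_frequent",
    "extract_closed",
    "itemset_to_bicluster",
    "verify_closedness",
    "mine_closed",
    "ExpressionMatrix",
    "binarize",
    "read_expression",
    "enumerate_frequent_bruteforce",
    "enumerate_closed_bruteforce",
    "enumerate_maximal_biclusters_bruteforce",
    "random_binary",
    "implant_blocks",
]
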
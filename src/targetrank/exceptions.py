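"""Exception hierarchy for targetrank."""


class TargetRankError(Exception):
    """Base class for all targetrank errors."""


class ConfigurationError(TargetRankError):
    """Invalid configuration, e.g. a missing required column or bad scheme name."""


class EmptyLexiconError(TargetRankError):
    """A gene lexicon source contained no usable entries."""


class UntokenizedLexiconError(TargetRankError):
    """An operation requiring token ids was called on an untokenized lexicon."""


class ContractError(TargetRankError):
    """A language-model adapter violated the CausalLM behavioural contract."""


class DegenerateResultError(TargetRankError):
    """A statistic is undefined for the given inputs (e.g. no finite paths)."""
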
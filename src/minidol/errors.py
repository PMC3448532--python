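"""Exception hierarchy for the toolkit."""


class MiniDolError(Exception):
    """Base class for all toolkit errors."""


class DialectSyntaxError(MiniDolError):
    """Malformed dialect source; carries a 1-based line and column."""

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class ExpressivityError(MiniDolError):
    """A construct was used that the declared logic does not admit."""

    def __init__(self, construct: str, logic: str):
        super().__init__(f"construct {construct!r} is not allowed in logic {logic}")
        self.construct = construct
        self.logic = logic


class BoundExceededError(MiniDolError):
    """Second-order evaluation refused: domain larger than the configured bound."""


class UntranslatableError(MiniDolError):
    """No path in the logic translation graph between the two logics."""

    def __init__(self, source: str, target: str):
        super().__init__(f"no translation path from {source} to {target}")
        self.source = source
        self.target = target


class InfeasibleBoundError(MiniDolError):
    """The domain bound is below the number of individuals forced distinct."""


class SignatureClashError(MiniDolError):
    """The same name is used in two different signature categories."""


class LinkError(MiniDolError):
    """A distributed-ontology link references an unknown module or edge."""


class CombineError(MiniDolError):
    """An alignment identification forces a signature-category clash."""
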
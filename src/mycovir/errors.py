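"""Exception hierarchy shared across the package."""


class MycovirError(Exception):
    """Base class for all package-specific errors."""


class EmptySequence(MycovirError):
    pass


class IllegalCharacter(MycovirError):
    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(f"illegal character {char!r} at offset {position}")


class LengthNotMultipleOfThree(MycovirError):
    pass


class ProteinShorterThanBins(MycovirError):
    pass


class MalformedRow(MycovirError):
    def __init__(self, row_index: int, n_columns: int):
        self.row_index = row_index
        self.n_columns = n_columns
        super().__init__(
            f"malformed domtblout row {row_index}: {n_columns} columns"
        )


class UncalibratedModel(MycovirError):
    pass


class WindowOutOfBounds(MycovirError):
    pass


class OrfOrderViolation(MycovirError):
    pass


class NoForwardOrf(MycovirError):
    pass


class IllegalPatternCharacter(MycovirError):
    pass


class LengthMismatch(MycovirError):
    pass


class AmbiguousExtension(MycovirError):
    pass


class AlphabetMismatch(MycovirError):
    pass


class DuplicateLabel(MycovirError):
    pass


class RaggedAlignment(MycovirError):
    pass


class UnknownTaxon(MycovirError):
    pass


class UnknownFamily(MycovirError):
    pass


class OverrideOutOfRange(MycovirError):
    pass


class ReadLongerThanSegment(MycovirError):
    pass


class MissingColumn(MycovirError):
    pass


class InvalidClass(MycovirError):
    pass
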
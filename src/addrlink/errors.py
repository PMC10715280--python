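"""Exception types raised across the linkage pipeline."""


class AddrlinkError(Exception):
    """Base class for all package errors."""


class SchemaError(AddrlinkError):
    """A table or feature vector does not conform to the configured schema."""


class IntegrityError(AddrlinkError):
    """Conflicting rows for one identifier in the gazetteer."""


class ReferenceLookupError(AddrlinkError):
    """An alias or annotation refers to an identifier absent from the gazetteer."""


class EmptyInputError(AddrlinkError):
    """An input address is empty, or cleaning removed every character."""


class BlockingError(AddrlinkError):
    """Tree-search blocking could not locate a plausible local area."""

    def __init__(self, message: str = "no tree node scored above the floor", stage: str = "blocking"):
        super().__init__(message)
        self.stage = stage


class TrainingError(AddrlinkError):
    """The matcher cannot be trained (e.g. single-class training data)."""
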
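"""Exception hierarchy.

Validation findings are never raised — they go into a report. Exceptions are
reserved for misuse of the API (unknown names, bad arguments) and for inputs
that cannot be parsed at all.
"""


class BenchmarkError(Exception):
    """Base class for all package errors."""


class SchemaError(BenchmarkError):
    """The bundled schema definition is malformed (fatal configuration error)."""


class UnknownClassError(BenchmarkError, KeyError):
    def __init__(self, name: str, known: list[str]):
        self.name = name
        self.known = known
        super().__init__(
            f"unknown class {name!r}; registered classes: {', '.join(known)}"
        )

    def __str__(self) -> str:  # KeyError quotes repr(args) otherwise
        return self.args[0]


class UnknownEnumError(BenchmarkError, KeyError):
    def __init__(self, name: str, known: list[str]):
        self.name = name
        self.known = known
        super().__init__(
            f"unknown enum {name!r}; registered enums: {', '.join(known)}"
        )

    def __str__(self) -> str:
        return self.args[0]


class FieldTypeError(BenchmarkError, TypeError):
    """A field value cannot be losslessly coerced to its declared type."""

    def __init__(self, class_name: str, field_name: str, expected: str, value: object):
        self.class_name = class_name
        self.field_name = field_name
        self.expected = expected
        super().__init__(
            f"{class_name}.{field_name}: expected {expected}, "
            f"got {type(value).__name__} {value!r}"
        )


class BundleParseError(BenchmarkError, ValueError):
    """A metadata document cannot be interpreted as a bundle at all."""

    def __init__(self, message: str, location: str = ""):
        self.location = location
        super().__init__(f"{message}" + (f" (at {location})" if location else ""))


class FormatDetectionError(BenchmarkError):
    """No sanctioned container format, or more than one, matches a store."""

    def __init__(self, message: str, code: str = "UNRECOGNIZED_FORMAT"):
        self.code = code
        super().__init__(message)


class ContainerError(BenchmarkError):
    """Container metadata is missing or malformed."""

    def __init__(self, message: str, key_path: str = ""):
        self.code = "CONTAINER_MALFORMED"
        self.key_path = key_path
        super().__init__(f"{message}" + (f" (at {key_path})" if key_path else ""))
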
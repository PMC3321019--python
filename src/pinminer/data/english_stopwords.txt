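a
about
above
after
again
all
also
an
and
any
are
as
at
be
because
been
before
being
between
both
but
by
can
cell
cells
could
did
do
does
down
during
each
few
for
from
further
had
has
have
having
here
how
however
if
in
into
is
it
its
large
level
levels
may
might
more
most
much
must
new
no
nor
not
now
of
off
on
once
only
or
other
our
out
over
own
patient
patients
protein
proteins
results
same
should
since
so
some
study
such
than
that
the
their
then
there
these
they
this
those
through
to
under
until
up
very
was
we
were
what
when
where
which
while
who
why
will
with
would
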
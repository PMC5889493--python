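a
about
above
across
act
add
afraid
after
afternoon
again
against
age
ago
agree
air
all
almost
alone
along
already
also
always
am
among
an
and
angry
animal
another
answer
any
anyone
anything
apple
are
arm
around
arrive
art
as
ask
at
ate
aunt
away
baby
back
bad
bag
ball
banana
band
bank
base
basket
bath
be
bean
bear
beat
beautiful
became
because
become
bed
bee
been
before
began
begin
behind
being
believe
bell
belong
below
belt
bench
bend
beside
best
better
between
big
bird
birthday
bit
bite
black
blanket
blew
blind
block
blood
blow
blue
board
boat
body
bone
book
boot
born
borrow
both
bottle
bottom
bought
bowl
box
boy
branch
brave
bread
break
breakfast
bridge
bright
bring
broke
brother
brought
brown
brush
build
built
burn
bus
busy
but
butter
button
buy
by
cake
call
came
camp
can
candy
cap
car
card
care
careful
carry
cat
catch
caught
cause
cent
chair
chance
change
chase
cheap
check
cheese
chicken
chief
child
children
choose
church
circle
city
class
clean
clear
climb
clock
close
cloth
cloud
coat
cold
color
come
cook
cool
copy
corn
corner
cost
cotton
could
count
country
course
cover
cow
cross
crowd
cry
cup
cut
dad
dance
dark
day
dead
dear
decide
deep
deer
desk
did
die
different
dig
dinner
dish
do
doctor
does
dog
doll
dollar
done
door
down
draw
dream
dress
drink
drive
drop
drove
dry
duck
during
dust
each
ear
early
earn
earth
east
easy
eat
edge
egg
eight
either
else
empty
end
enjoy
enough
even
evening
ever
every
everyone
everything
except
eye
face
fact
fall
family
far
farm
farmer
fast
fat
father
feed
feel
feet
fell
felt
fence
few
field
fight
fill
find
fine
finger
finish
fire
first
fish
fit
five
fix
flag
flat
flew
floor
flower
fly
follow
food
foot
for
forest
forget
forgot
form
found
four
fox
free
fresh
friend
from
front
fruit
full
fun
funny
game
garden
gate
gave
get
gift
girl
give
glad
glass
go
goat
god
goes
going
gold
gone
good
got
grade
grain
grand
grass
gray
great
green
grew
ground
group
grow
guess
had
hair
half
hand
hang
happen
happy
hard
has
hat
have
he
head
hear
heard
heart
heavy
held
hello
help
hen
her
here
herself
hid
hide
high
hill
him
himself
his
hit
hold
hole
holiday
home
hope
horse
hot
hour
house
how
hundred
hungry
hunt
hurry
hurt
ice
idea
if
ill
important
in
inch
inside
into
iron
is
it
its
itself
job
join
joke
joy
jump
just
keep
kept
key
kick
kill
kind
king
kiss
kitchen
kite
knee
knew
knife
knock
know
ladder
lady
lake
land
large
last
late
laugh
lay
lazy
lead
leaf
learn
least
leave
left
leg
lemon
less
let
letter
lie
life
lift
light
like
line
lion
lip
list
listen
little
live
long
look
lost
lot
loud
love
low
luck
lunch
machine
made
mail
make
man
many
map
march
mark
market
matter
may
me
mean
meat
meet
men
met
middle
might
mile
milk
mind
mine
minute
miss
moment
money
month
moon
more
morning
most
mother
mountain
mouse
mouth
move
much
mud
music
must
my
name
near
neck
need
neighbor
nest
never
new
next
nice
night
nine
no
noise
noon
north
nose
not
note
nothing
now
number
nurse
nut
ocean
of
off
office
often
oh
oil
old
on
once
one
only
open
or
orange
order
other
our
out
outside
over
own
page
paid
pail
paint
pair
pan
paper
parent
park
part
party
pass
past
pay
pen
pencil
penny
people
perhaps
person
pick
picture
pie
piece
pig
pin
place
plan
plant
play
please
pocket
point
pond
poor
post
pot
potato
pound
pour
practice
present
pretty
price
print
prize
promise
proud
pull
push
put
queen
question
quick
quiet
quite
rabbit
race
radio
rain
raise
ran
reach
read
ready
real
red
remember
rest
ride
right
ring
river
road
rock
roll
roof
room
rope
rose
round
row
rub
rule
run
sad
safe
said
sail
salt
same
sand
sang
sat
save
saw
say
school
sea
seat
second
see
seed
seem
seen
sell
send
sent
set
seven
several
shake
shall
shape
share
sharp
she
sheep
shine
ship
shirt
shoe
shop
short
should
shoulder
shout
show
sick
side
sign
silver
simple
since
sing
sister
sit
six
size
skin
sky
sleep
slow
small
smell
smile
smoke
snow
so
soap
sock
soft
sold
some
someone
something
sometimes
son
song
soon
sorry
sound
soup
south
space
speak
spell
spend
spent
spoke
spoon
sport
spot
spread
spring
square
stand
star
start
stay
step
stick
still
stone
stood
stop
store
story
straight
strange
street
strong
such
sudden
sugar
summer
sun
supper
sure
surprise
sweet
swim
table
tail
take
talk
tall
taste
teach
teacher
team
tear
teeth
tell
ten
tent
than
thank
that
the
their
them
then
there
these
they
thick
thin
thing
think
third
this
those
though
thought
three
through
throw
tie
time
tiny
tired
to
today
toe
together
told
tomorrow
too
took
tooth
top
touch
toward
town
toy
train
tree
trick
trip
truck
true
try
turn
twelve
twenty
two
ugly
uncle
under
understand
until
up
upon
us
use
usual
valley
very
visit
voice
wagon
wait
wake
walk
wall
want
war
warm
was
wash
watch
water
wave
way
we
wear
weather
week
well
went
were
west
wet
what
wheel
when
where
which
while
white
who
whole
whose
why
wide
wife
wild
will
win
wind
window
wing
winter
wish
with
without
woke
woman
women
wonder
wood
word
wore
work
world
would
write
wrong
yard
year
yellow
yes
yesterday
yet
you
young
your
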
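# Demonstration pro-environmental behaviour phrase list (synthetic stand-in
# for a validated questionnaire item bank). Exactly seven categories; phrases
# are matched case-insensitively as substrings of the raw post text.

[saving_energy]
save energy
turn off the lights
energy saving
low carbon
solar panel

[consumption]
buy less
second hand
reusable bag
eco friendly product
green product

[activism]
climate protest
sign the petition
environmental campaign
climate action
earth hour

[recycling]
recycle
recycling
sort the trash
compost
reuse

[transportation]
ride a bike
public transport
take the bus
carpool
electric car

[diets]
plant based
eat less meat
vegetarian
vegan
local food

[waste_management]
food waste
zero waste
plastic free
litter less
waste sorting
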